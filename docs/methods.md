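# Methods

## The model

MD-TSPC4 rests on one empirical assumption: within the temperature
range where an i-motif stays folded, its conformational flexibility in
simulation correlates with its thermal stability in solution. Single
simulation temperatures correlate poorly for long-loop i-motifs, so the
flexibility statistic averages over a temperature ladder:

- per temperature *T*, the best-fit RMSD of the whole molecule against
  the trajectory's first frame is time-averaged over the run;
- RMSD̄(T) is the arithmetic mean of those averages over the ladder
  (default 280, 300, 320, 340, 360 K — five temperatures bracketing the
  melting range of the reference i-motifs);
- experimental CD melting temperatures of reference sequences are
  regressed on RMSD̄(T) by ordinary least squares (the TR plot), and the
  line predicts Tm for new sequences.

The shipped calibration (`published_calibration()`) uses the
whole-molecule RMSD̄(T) of the three thymine-loop models — 2.0, 3.4,
5.0 Å for CCCT3/CCCT5/CCCT7 — against their measured Tm of 332, 321,
311 K, giving slope −6.98 K/Å and intercept 345.54 K. The calibration
deliberately stores x-values at the one-decimal precision at which the
flexibility summaries are conventionally reported: re-fitting the
stored points reproduces the stored coefficients to two decimals.
`fit_tr_plot` accepts unrounded points for users who keep full
precision. Note the computed R² of the three stored points is 0.9957;
the stored `r_squared` keeps the conventional two-decimal 0.99.

Predictions are reported at full precision and rounded to the nearest
kelvin (the reporting convention for CD melting temperatures).
Predictions outside the calibration's RMSD̄(T) range are permitted —
novel sequences are the method's purpose — but flagged as
extrapolations. Nothing restricts the ladder to five temperatures; any
set of ≥2 is accepted, with the five-point ladder as the documented
default.

## Sequence and pairing conventions

Residues are numbered 1-based, 5′→3′; spans are inclusive. On a plain
sequence, a tract is a maximal run of ≥2 consecutive cytosines; exactly
four equal-length tracts separated by three non-empty loops are
required, and anything else is a loud parse error. This matches every
common model i-motif while refusing ambiguous inputs.

The C:C⁺ pair topology pairs tract 1 with 3 and tract 2 with 4
(2 × tract-length pairs, each cytosine in at most one pair). Two
intercalation registers are provided because the register of the
experimentally derived template is not uniquely determined by pair
nomenclature alone: `aligned` pairs the i-th cytosine of a tract with
the i-th of its partner; `shifted` offsets the partner by one position
cyclically (producing names such as C2c:C4a at tract length 3).
Neither is asserted as *the* native register; `aligned` is the default
and the toy-structure generator realises it geometrically.

## Trajectory statistics

- **Superposition** is Kabsch via `scipy.spatial.transform.Rotation.align_vectors`
  (proper rotation, optional weights). Collinear or coincident clouds
  have no unique rotation; they fall back to a translation-only fit
  flagged `degenerate`.
- **RMSD** superposes each frame onto the reference using the same
  atom mask being measured (per-mask fitting, the behaviour of the
  standard MD post-processing tools); a separate `fit_selection`
  supports measuring loop motion in the core frame. The reference
  defaults to the first frame, so series start at 0. Heavy atoms only
  by default; hydrogens on request.
- **Time averages** use the full series (burn-in 0 ps) unless a burn-in
  is given, since the reference protocol averages whole runs.
- **RMSF** is computed per atom about its trajectory-mean position and
  root-mean-square-combined per residue.
- **RDF** histograms reference→target distances (bin width 0.1 Å, range
  10 Å by default) normalised by the ideal-gas expectation at the
  reference density (default 0.03 molecules·Å⁻³ ≈ water at 1 g/mL)
  using the physical shell volume (4π/3)((R+dR)³ − R³). A second
  normalisation mode, `literal`, replaces the subtracted term with
  (dR)³; it is kept selectable for comparison with that variant
  formula but is not the physical expectation. Minimum-image periodic
  distances are applied when a cubic box is given.
- **C:C⁺ monitoring** follows each pair's N3–N3 distance. "Hydrogen-bond
  distance" is operationalised as ≤3.5 Å (the conventional heavy-atom
  donor–acceptor limit); a pair is *disrupted* when it exceeds the
  cutoff in >50% of frames. Both numbers are parameters.
- **Loop contacts** count frames with any inter-loop heavy-atom
  distance <4.0 Å (a common contact criterion).

## CD melting analysis

Tm (heating) and Ta (annealing) are the extremum of the first
derivative of 285 nm ellipticity with respect to temperature. The
implementation differentiates with a Savitzky–Golay filter (window 11
points ≈ 2.2 K at the standard 0.2 K pitch, cubic), which at realistic
noise leaves derivative noise comparable to the transition peak; the
extremum is therefore located in two stages: a coarse argmax on a
second, wider (~8 K) smoothing pass — which cannot shift a symmetric
peak — followed by a least-squares Gaussian-peak fit to the
(sign-corrected) derivative, falling back to parabolic refinement if
the fit fails. On synthetic two-state curves this recovers midpoints to
<0.05 K mean error at 2% amplitude noise while remaining a pure
first-derivative method (no thermodynamic model is fitted). Curves
whose smoothed derivative shows no interior extremum above 2× the
median absolute derivative raise a no-transition error; this correctly
rejects flat and purely linear baselines. Extraction is invariant to
ellipticity offset and uniform scaling, and heating vs reversed
annealing agree exactly on noiseless data. Celsius inputs (all
temperatures <200) are auto-converted to kelvin on load.

The i-motif spectral signature check looks for a positive maximum in
275–295 nm, a negative minimum in 255–275 nm, and a ≥2:1 amplitude
ratio.

## Synthetic data: what it emulates and what it does not

The generators exist to give every operator an input with known ground
truth, not to mimic MD physics. Trajectory noise is i.i.d. Gaussian per
atom, coordinate and frame — no autocorrelation, no anisotropy, no
actual dynamics — because that makes expectations closed-form: unfitted
RMSF = σ√3, unfitted per-frame mean-square deviation = 3σ² (per atom),
and fitting removes six rigid-body degrees of freedom, ≈3σ²(1−2/N).
Consequently, passing tests demonstrate that the *operators* are
correct, not that real MD trajectories of real i-motifs would yield any
particular RMSD̄(T).

`make_temperature_trajectory_set` can tune amplitudes to hit target
per-temperature RMSD averages: the closed-form σ above initialises a
fixed-point iteration (regenerate with the same per-temperature seed,
rescale σ by target/measured) that converges to 0.5% relative error in
a few iterations. This provides end-to-end pipeline fixtures whose
correct answer is known analytically.

The pseudo-atom i-motif (one bead per residue, named N3, unit mass)
realises the aligned register exactly: tract-1/3 beads sit 2.8 Å apart
along x, tract-2/4 along y, with pair planes interleaved by rise/2
(rise 3.1 Å); loops arc outward on distinct diagonals. It carries no
base geometry, no backbone, and no sterics.

Melt curves are two-state logistic mixes of linear baselines over
293–353 K at 0.2 K pitch (amplitude 6 mdeg, width 3 K by default, noise
given as an absolute mdeg sd — 0.12 for "2% of amplitude"). Ideal-gas
frames are uniform points in a periodic cube (density 0.03 Å⁻³, box
20 Å → 240 points/frame). All generators are bit-deterministic for a
fixed seed.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen so the analytic
tolerances are comfortably resolvable: 10⁴ frames for the σ√3 RMSF
check (Monte-Carlo error ≪ the 3% band), 50 ideal-gas frames
(≈1.4×10⁶ pair distances; mean |g−1| ≈ 0.03 against the 0.05 band),
300–400 frames per temperature for pipeline fixtures (amplitude tuning
to 0.5%, comfortably inside the 2% recovery band), and 100 seeded
replicates for melt-curve recovery. Numerical tolerances follow the
quantity: rigid-motion invariance to 1e-6 Å, OLS identities to 1e-6,
exact arithmetic to machine precision.

## Known limitations

- The calibration derives from three thymine-loop model sequences plus
  two validation cases; it is not a general-purpose Tm predictor for
  arbitrary sequence space, pH or ionic conditions (pH effects in
  particular are unmodelled).
- The package analyses trajectories; it does not produce them. Real
  predictions require an external MD engine, force field and
  protonation setup.
- No MMGBSA-style energetics, no solvent handling beyond stripped
  trajectories, no periodic imaging of raw MD boxes (the RDF's
  minimum-image support targets the point-cloud fixtures).
- Tm extraction assumes an approximately two-state, roughly symmetric
  transition; multi-phasic melts will report the dominant transition
  only.
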