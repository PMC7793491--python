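"""Region-aware trajectory statistics on a synthetic i-motif trajectory.

Builds a pseudo-atom CCCT3 model, adds Gaussian positional noise with
flexible loops (sigma 0.9 A/coordinate) and a stiff core (0.3 A), and
computes the standard flexibility observables.
"""

import numpy as np

from tspc4 import (
    AtomSelection,
    assign_regions,
    build_cc_pair_topology,
    cc_pair_distances,
    parse_imotif_notation,
    radius_of_gyration_series,
    rdf,
    rmsd_series,
    rmsf_per_residue,
    select_atoms,
    time_average_rmsd,
)
from tspc4.synthetic import (
    FluctuationSpec,
    make_gaussian_trajectory,
    make_ideal_gas_frames,
    make_toy_imotif_structure,
)

seq = parse_imotif_notation("d[(CCCTTT)3CCC]", name="CCCT3")
structure = make_toy_imotif_structure(seq)
regions = assign_regions(seq)
traj = make_gaussian_trajectory(
    structure,
    FluctuationSpec(sigma={"core": 0.3, "loop": 0.9}, seed=11),
    n_frames=2000,
    regions=regions,
)

# time-averaged best-fit RMSD per region (reference = first frame)
for region in ("whole", "core", "loop"):
    sel = select_atoms(structure, AtomSelection(region=region), regions)
    avg = time_average_rmsd(rmsd_series(traj, sel))
    print(f"average RMSD, {region:5s}: {avg:.2f} A")

# per-residue RMSF: loops fluctuate ~3x more than the core by construction
whole = select_atoms(structure, AtomSelection("whole"), regions)
rmsf = rmsf_per_residue(traj, whole, fit=False)
core_mean = np.mean([rmsf[r] for r in regions.residues("core")])
loop_mean = np.mean([rmsf[r] for r in regions.residues("loop")])
print(f"mean RMSF core {core_mean:.2f} A, loops {loop_mean:.2f} A "
      f"(expected ~ sigma*sqrt(3): 0.52 vs 1.56)")

# radius of gyration reports overall compactness
rg = radius_of_gyration_series(traj, whole)
print(f"mean Rg: {rg.values.mean():.2f} A")

# C:C+ N3-N3 monitoring: the native model keeps all pairs within H-bond range
topology = build_cc_pair_topology(seq)
report = cc_pair_distances(traj, topology, seq)
print(f"pair status: {dict(zip(report.pair_names, report.status))}")

# RDF sanity check: a uniform gas at the reference density gives g(r) ~ 1
gas = make_ideal_gas_frames(density=0.03, box=20.0, n_frames=20, seed=12)
idx = np.arange(gas.n_atoms)
profile = rdf(gas, idx, idx, box=20.0)
print(f"ideal-gas RDF mean |g-1|: {np.mean(np.abs(profile.g_of_r - 1)):.3f}")
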