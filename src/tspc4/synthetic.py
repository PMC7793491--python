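"""Synthetic fixtures with closed-form ground truth for every analysis stage.

These generators stand in for MD engine output and CD instrument data at
desk scale.  Trajectory noise is i.i.d. Gaussian per atom and frame (no
autocorrelation), which makes the RMSD/RMSF expectations closed-form:
with per-coordinate standard deviation sigma and no superposition, the
expected per-residue RMSF is sigma*sqrt(3) and the expected per-frame
mean-square deviation is 3*sigma^2.  Superposition onto a reference
removes six rigid-body degrees of freedom, so the fitted expectation
over N atoms is approximately 3*sigma^2*(1 - 2/N).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import DEFAULT_TEMPERATURES
from .errors import AnalysisError
from .io import Atom, Structure, Trajectory
from .melting import MeltCurve
from .sequence import CCPairTopology, IMotifSequence, RegionMap
from .stats import rmsd_series, time_average_rmsd

__all__ = [
    "FluctuationSpec",
    "make_toy_imotif_structure",
    "make_gaussian_trajectory",
    "make_temperature_trajectory_set",
    "make_melt_curve",
    "make_ideal_gas_frames",
    "make_pair_drift_trajectory",
]

_BASE_RESNAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


@dataclass(frozen=True)
class FluctuationSpec:
    """Per-region positional noise amplitudes (A per coordinate) + seed.

    ``sigma`` maps region labels (``core``, ``loop1``..``loop3``; the
    key ``loop`` applies to all loops) to the standard deviation of the
    isotropic Gaussian displacement applied independently per atom,
    coordinate and frame.  A plain float applies everywhere.
    """

    sigma: float | Mapping[str, float] = 0.5
    seed: int = 0

    def sigma_for(self, label: str) -> float:
        if isinstance(self.sigma, (int, float)):
            return float(self.sigma)
        if label in self.sigma:
            return float(self.sigma[label])
        if label.startswith("loop") and "loop" in self.sigma:
            return float(self.sigma["loop"])
        raise AnalysisError(f"no sigma given for region {label!r}")


def make_toy_imotif_structure(
    seq: IMotifSequence,
    rise: float = 3.1,
    pair_distance: float = 2.8,
    loop_radius: float = 6.0,
) -> Structure:
    """Deterministic pseudo-atom model of an i-motif (one bead per residue).

    Every residue is represented by a single bead named ``N3`` (unit
    mass) so that C:C+ pair-distance and region logic are exercisable
    without a force field.  Core beads are placed as two intercalated
    stacks: tract 1/3 pairs lie along x and tract 2/4 pairs along y,
    with successive pair planes separated by ``rise``/2 along z, giving
    every aligned-register N3-N3 pair distance exactly
    ``pair_distance``.  Loop beads sit on arcs of radius ``loop_radius``
    connecting the tract ends.
    """
    if rise <= 0:
        raise AnalysisError("rise must be positive (degenerate stacking)")
    if pair_distance <= 0:
        raise AnalysisError("pair_distance must be positive")
    L = seq.tract_length
    half = pair_distance / 2.0
    coords = np.zeros((seq.n_residues, 3))

    # core: tract1/tract3 rungs at z = k*rise, tract2/tract4 offset by rise/2
    for k in range(L):
        z13 = k * rise
        z24 = k * rise + rise / 2.0
        coords[seq.tracts[0][0] - 1 + k] = (-half, 0.0, z13)
        coords[seq.tracts[2][0] - 1 + k] = (+half, 0.0, z13)
        coords[seq.tracts[1][0] - 1 + k] = (0.0, -half, z24)
        coords[seq.tracts[3][0] - 1 + k] = (0.0, +half, z24)

    # loops: semicircular arcs fanned out in distinct directions
    arc_dirs = ((1.0, 1.0), (-1.0, 1.0), (-1.0, -1.0))
    top_z = (L - 1) * rise + rise / 2.0
    for n, (lo, hi) in enumerate(seq.loops):
        m = hi - lo + 1
        ux, uy = arc_dirs[n]
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        for j in range(m):
            # angle sweeps 0..pi over the loop; radius bulges mid-loop
            theta = math.pi * (j + 1) / (m + 1)
            r = loop_radius * math.sin(theta) + half
            z = top_z + rise * math.sin(theta)
            coords[lo - 1 + j] = (ux * r, uy * r, z)

    atoms = tuple(
        Atom(
            name="N3",
            element="N",
            residue_index=i + 1,
            residue_name=_BASE_RESNAMES.get(base, "UNK"),
            mass=1.0,
        )
        for i, base in enumerate(seq.sequence)
    )
    return Structure(atoms=atoms, coordinates=coords)


def make_gaussian_trajectory(
    structure: Structure,
    spec: FluctuationSpec,
    n_frames: int,
    regions: RegionMap | None = None,
    frame_interval: float = 0.5,
    noisy_first_frame: bool = False,
) -> Trajectory:
    """Reference structure + i.i.d. Gaussian positional noise per frame.

    Per-atom noise amplitude follows the atom's region label in
    ``regions`` (uniform ``spec.sigma`` when no map is given).  By
    default the first frame is the unperturbed reference, matching the
    convention that RMSD series start at zero.
    """
    if n_frames < 2:
        raise AnalysisError("need n_frames >= 2")
    n = structure.n_atoms
    sigmas = np.empty(n)
    if regions is None:
        if not isinstance(spec.sigma, (int, float)):
            raise AnalysisError("per-region sigma requires a RegionMap")
        sigmas[:] = float(spec.sigma)
    else:
        if structure.n_residues > len(regions):
            raise AnalysisError(
                "region map does not cover the structure's residues"
            )
        for i, atom in enumerate(structure.atoms):
            sigmas[i] = spec.sigma_for(regions.labels[atom.residue_index - 1])
    if np.any(sigmas < 0):
        raise AnalysisError("sigma must be non-negative")

    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((n_frames, n, 3)) * sigmas[None, :, None]
    if not noisy_first_frame:
        noise[0] = 0.0
    frames = structure.coordinates[None, :, :] + noise
    return Trajectory(
        topology=structure, frames=frames, frame_interval=frame_interval
    )


def _measure_whole_rmsd_average(traj: Trajectory) -> float:
    sel = np.arange(traj.n_atoms)
    return time_average_rmsd(rmsd_series(traj, sel))


def make_temperature_trajectory_set(
    structure: Structure,
    temps: Sequence[float] = DEFAULT_TEMPERATURES,
    n_frames: int = 400,
    schedule: Mapping[float, FluctuationSpec] | None = None,
    target_rmsd: Sequence[float] | None = None,
    seed: int = 0,
    regions: RegionMap | None = None,
    rmsd_tolerance: float = 0.005,
) -> dict[float, Trajectory]:
    """One Gaussian trajectory per temperature, optionally amplitude-tuned.

    With ``target_rmsd`` given (one value per temperature, Angstrom),
    the uniform noise amplitude at each temperature is solved so that
    the time-averaged, best-fit whole-molecule RMSD of the generated
    trajectory matches the target: the closed-form initial guess
    sigma = target / sqrt(3 (1 - 2/N)) is refined by fixed-point
    rescaling against the empirically measured average (same noise
    draws each iteration), converging to ``rmsd_tolerance`` relative
    error.  Without targets, ``schedule`` supplies a FluctuationSpec
    per temperature.
    """
    temps = tuple(float(t) for t in temps)
    if target_rmsd is not None:
        if len(target_rmsd) != len(temps):
            raise AnalysisError("need one target RMSD per temperature")
        if any(t < 0 for t in target_rmsd):
            raise AnalysisError("target RMSD values must be non-negative")
    elif schedule is None:
        raise AnalysisError("give either target_rmsd or a sigma schedule")
    else:
        missing = [t for t in temps if t not in schedule]
        if missing:
            raise AnalysisError(f"schedule missing temperatures {missing}")

    n = structure.n_atoms
    out: dict[float, Trajectory] = {}
    for j, temp in enumerate(temps):
        sub_seed = (seed * 1009 + j * 101) % (2**31)
        if target_rmsd is None:
            spec = schedule[temp]
            out[temp] = make_gaussian_trajectory(
                structure, spec, n_frames, regions=regions
            )
            continue
        target = float(target_rmsd[j])
        if target == 0.0:
            out[temp] = make_gaussian_trajectory(
                structure, FluctuationSpec(sigma=0.0, seed=sub_seed), n_frames
            )
            continue
        sigma = target / math.sqrt(3.0 * max(1.0 - 2.0 / n, 0.1))
        traj = None
        for _ in range(6):
            traj = make_gaussian_trajectory(
                structure, FluctuationSpec(sigma=sigma, seed=sub_seed), n_frames
            )
            measured = _measure_whole_rmsd_average(traj)
            if abs(measured - target) / target <= rmsd_tolerance:
                break
            sigma *= target / measured
        out[temp] = traj
    return out


def make_melt_curve(
    tm: float,
    width: float = 3.0,
    amplitude: float = 6.0,
    baseline: float = 0.5,
    baseline_slopes: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    t_range: tuple[float, float] = (293.0, 353.0),
    pitch: float = 0.2,
    seed: int = 0,
    direction: str = "heating",
) -> MeltCurve:
    """Two-state sigmoidal CD melt curve with optional Gaussian noise.

    Ellipticity follows folded/unfolded linear baselines mixed by the
    logistic folded fraction f(T) = 1/(1+exp((T-tm)/width)); on heating
    the 285 nm signal therefore decreases through an inflection at
    ``tm``.  Defaults mimic the standard acquisition: 293-353 K at
    0.2 K pitch, folded level ``baseline + amplitude`` mdeg decaying to
    ``baseline``.
    """
    lo, hi = t_range
    if not (lo < tm < hi):
        raise AnalysisError(f"tm {tm} K outside the scan range {t_range}")
    if width <= 0 or pitch <= 0:
        raise AnalysisError("width and pitch must be positive")
    t = np.arange(lo, hi + pitch / 2.0, pitch)
    folded_frac = 1.0 / (1.0 + np.exp((t - tm) / width))
    pre = baseline + amplitude + baseline_slopes[0] * (t - tm)
    post = baseline + baseline_slopes[1] * (t - tm)
    theta = post + (pre - post) * folded_frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.standard_normal(t.size) * noise_sd
    if direction == "annealing":
        t, theta = t[::-1].copy(), theta[::-1].copy()
    return MeltCurve(
        temperatures=t, ellipticity=theta, direction=direction
    )


def make_ideal_gas_frames(
    density: float = 0.03,
    box: float = 20.0,
    n_frames: int = 20,
    seed: int = 0,
) -> Trajectory:
    """Uniform random points in a periodic cube at the stated density.

    The default 0.03 molecules/A^3 matches the conventional reference
    density (water at ~1 g/mL); box 20 A then holds 240 points per
    frame.  The fixture's g(r) is 1 at all r in expectation.
    """
    if density <= 0 or box <= 0:
        raise AnalysisError("density and box must be positive")
    n_points = int(round(density * box**3))
    if n_points < 2:
        raise AnalysisError(
            f"box too small: density {density} in box {box} A gives "
            f"{n_points} point(s)"
        )
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0.0, box, size=(n_frames, n_points, 3))
    atoms = tuple(
        Atom(name="O", element="O", residue_index=i + 1,
             residue_name="HOH", mass=18.015)
        for i in range(n_points)
    )
    structure = Structure(atoms=atoms, coordinates=frames[0])
    return Trajectory(topology=structure, frames=frames)


def make_pair_drift_trajectory(
    structure: Structure,
    topology: CCPairTopology,
    seq: IMotifSequence,
    drifting_pair: str,
    drift_distance: float = 8.0,
    drift_fraction: float = 0.6,
    n_frames: int = 100,
) -> Trajectory:
    """Static trajectory in which one C:C+ pair opens in a known fraction of frames.

    In ``round(drift_fraction * n_frames)`` frames (taken from the end,
    so the first frame stays native) the second partner of
    ``drifting_pair`` is displaced radially until the pair's N3-N3
    distance equals ``drift_distance``; everything else never moves.
    """
    if not (0.0 <= drift_fraction <= 1.0):
        raise AnalysisError("drift_fraction must be in [0, 1]")
    pair = topology.by_name(drifting_pair)  # KeyError if absent
    res_i, res_j = pair.residue_indices(seq)
    idx_i = idx_j = None
    for i, atom in enumerate(structure.atoms):
        if atom.name == "N3" and atom.residue_index == res_i:
            idx_i = i
        if atom.name == "N3" and atom.residue_index == res_j:
            idx_j = i
    if idx_i is None or idx_j is None:
        raise AnalysisError(f"pair {drifting_pair} lacks an N3 bead in the structure")

    base = structure.coordinates
    vec = base[idx_j] - base[idx_i]
    d0 = np.linalg.norm(vec)
    if d0 == 0:
        raise AnalysisError("paired beads are coincident")
    displaced = base.copy()
    displaced[idx_j] = base[idx_i] + vec / d0 * drift_distance

    n_drift = int(round(drift_fraction * n_frames))
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if n_drift:
        frames[n_frames - n_drift :] = displaced[None, :, :]
    return Trajectory(topology=structure, frames=frames)
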