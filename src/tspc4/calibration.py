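"""MD-TSPC4 thermal-stability calibration and prediction (the TR plot).

The method summarises an i-motif's conformational flexibility as
RMSD_bar(T): the arithmetic mean over a set of simulation temperatures
(280, 300, 320, 340, 360 K by default) of the time-averaged, whole-
molecule best-fit RMSD at each temperature.  Experimental melting
temperatures of reference i-motifs are regressed linearly on
RMSD_bar(T) — the TR plot — and the fitted line

    Tm = slope * RMSD_bar(T) + intercept

predicts Tm for new sequences from simulation alone.  The published
calibration, built from the three thymine-loop model i-motifs CCCT3,
CCCT5 and CCCT7, is

    Tm = -6.98 * RMSD_bar(T) + 345.54   (R^2 = 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import AnalysisError
from .io import AtomSelection, Trajectory, select_atoms
from .sequence import IMotifSequence, assign_regions
from .stats import rmsd_series, time_average_rmsd

__all__ = [
    "DEFAULT_TEMPERATURES",
    "REFERENCE_RMSD_TABLE",
    "TRCalibration",
    "TmPrediction",
    "PipelineReport",
    "mean_rmsd_over_temperatures",
    "fit_tr_plot",
    "predict_tm",
    "published_calibration",
    "run_md_tspc4",
]

#: Simulation temperature set of the standard protocol (K).
DEFAULT_TEMPERATURES: tuple[float, ...] = (280.0, 300.0, 320.0, 340.0, 360.0)

#: Published time-averaged RMSD (Angstrom) per region and temperature for
#: the five model i-motifs, from 200 ns simulations at the default
#: temperature set.  Rows: 280..360 K; the reported per-model
#: RMSD_bar(T) values (to one decimal) are 2.0/3.4/5.0/4.1/2.1 A for the
#: whole molecule.
REFERENCE_RMSD_TABLE: pd.DataFrame = pd.DataFrame(
    {
        ("CCCT3", "whole"): [1.8, 1.9, 2.1, 2.1, 2.4],
        ("CCCT3", "core"): [1.2, 1.3, 1.2, 1.2, 1.2],
        ("CCCT3", "loop"): [3.5, 4.2, 4.4, 4.5, 4.5],
        ("CCCT5", "whole"): [3.8, 3.3, 3.0, 3.1, 4.0],
        ("CCCT5", "core"): [1.2, 1.1, 1.3, 1.0, 1.2],
        ("CCCT5", "loop"): [6.1, 4.9, 5.6, 5.9, 6.4],
        ("CCCT7", "whole"): [5.3, 4.6, 4.1, 5.4, 5.8],
        ("CCCT7", "core"): [1.5, 2.6, 1.9, 1.3, 1.4],
        ("CCCT7", "loop"): [7.0, 6.2, 5.9, 8.7, 7.7],
        ("CCCT6", "whole"): [3.5, 3.4, 4.3, 4.6, 4.8],
        ("CCCT6", "core"): [1.5, 0.9, 1.0, 2.3, 1.1],
        ("CCCT6", "loop"): [5.3, 5.4, 5.9, 7.2, 7.1],
        ("CCCTA2", "whole"): [1.9, 1.9, 2.1, 2.5, 2.2],
        ("CCCTA2", "core"): [1.4, 1.3, 1.3, 1.3, 1.5],
        ("CCCTA2", "loop"): [4.0, 4.3, 4.4, 4.8, 5.1],
    },
    index=pd.Index(DEFAULT_TEMPERATURES, name="temperature_K"),
)

#: Experimental CD melting temperatures (K) of the calibration models.
REFERENCE_TM: dict[str, float] = {"CCCT3": 332.0, "CCCT5": 321.0, "CCCT7": 311.0}


@dataclass(frozen=True)
class TRCalibration:
    """A fitted Tm-vs-RMSD_bar(T) line with its training points."""

    slope: float  # K per Angstrom
    intercept: float  # K
    r_squared: float
    points: tuple[tuple[float, float, str], ...]  # (rmsd_mean A, tm K, label)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise AnalysisError("a calibration needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0):
            raise AnalysisError(f"r_squared {self.r_squared} outside [0, 1]")

    @property
    def rmsd_range(self) -> tuple[float, float]:
        xs = [p[0] for p in self.points]
        return min(xs), max(xs)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "points": [list(p) for p in self.points],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TRCalibration":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            points=tuple((float(x), float(t), str(lab)) for x, t, lab in d["points"]),
        )


@dataclass(frozen=True)
class TmPrediction:
    """A predicted melting temperature with provenance."""

    tm: float  # K, full precision
    rmsd_mean: float  # Angstrom
    calibration: TRCalibration
    extrapolated: bool

    @property
    def tm_rounded(self) -> int:
        """Tm to the nearest kelvin, the conventional reporting precision."""
        return int(round(self.tm))


def mean_rmsd_over_temperatures(values: Iterable[float]) -> float:
    """RMSD_bar(T): arithmetic mean of per-temperature time-averaged RMSDs."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise AnalysisError("no per-temperature RMSD values given")
    if np.any(vals < 0):
        raise AnalysisError("RMSD values must be non-negative")
    return float(vals.mean())


def fit_tr_plot(
    points: Sequence[tuple[float, float] | tuple[float, float, str]]
) -> TRCalibration:
    """Ordinary-least-squares fit of Tm against RMSD_bar(T).

    ``points`` are (rmsd_mean, tm) or (rmsd_mean, tm, label) tuples.
    Returns slope (K/A), intercept (K) and R^2 = 1 - SSres/SStot.
    """
    labelled = [
        (float(p[0]), float(p[1]), str(p[2]) if len(p) > 2 else f"point{i+1}")
        for i, p in enumerate(points)
    ]
    if len(labelled) < 2:
        raise AnalysisError("need at least 2 calibration points")
    x = np.array([p[0] for p in labelled])
    y = np.array([p[1] for p in labelled])
    if np.allclose(x, x[0]):
        raise AnalysisError("calibration points have zero RMSD variance")
    res = sp_stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):
        # zero Tm variance: the flat line fits exactly
        residuals = y - (res.slope * x + res.intercept)
        r2 = 1.0 if np.allclose(residuals, 0.0) else 0.0
    return TRCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        points=tuple(labelled),
    )


def predict_tm(rmsd_mean: float, calibration: TRCalibration) -> TmPrediction:
    """Evaluate the calibration line at ``rmsd_mean`` (Angstrom).

    Predictions outside the calibration's RMSD_bar(T) range are allowed
    (the method's purpose is novel sequences) but flagged
    ``extrapolated``.
    """
    if rmsd_mean < 0:
        raise AnalysisError("RMSD_bar(T) must be non-negative")
    lo, hi = calibration.rmsd_range
    tm = calibration.slope * rmsd_mean + calibration.intercept
    return TmPrediction(
        tm=float(tm),
        rmsd_mean=float(rmsd_mean),
        calibration=calibration,
        extrapolated=not (lo <= rmsd_mean <= hi),
    )


def published_calibration() -> TRCalibration:
    """The published TR-plot calibration with its three training points.

    Training x-values are the reported one-decimal RMSD_bar(T) of
    CCCT3/CCCT5/CCCT7 (2.0, 3.4, 5.0 A) against their experimental Tm
    (332, 321, 311 K); re-fitting these points reproduces the stored
    coefficients to two decimals.
    """
    return TRCalibration(
        slope=-6.98,
        intercept=345.54,
        r_squared=0.99,
        points=(
            (2.0, 332.0, "CCCT3"),
            (3.4, 321.0, "CCCT5"),
            (5.0, 311.0, "CCCT7"),
        ),
    )


@dataclass(frozen=True)
class PipelineReport:
    """Full MD-TSPC4 output: per-temperature/per-region RMSD table + Tm."""

    sequence_name: str
    rmsd_table: pd.DataFrame  # index: temperature K; columns: whole/core/loop
    rmsd_mean: float  # whole-molecule RMSD_bar(T), Angstrom
    prediction: TmPrediction

    def summary(self) -> str:
        lines = [
            f"MD-TSPC4 report for {self.sequence_name}",
            "",
            "Time-averaged RMSD (A) per temperature and region:",
            self.rmsd_table.round(2).to_string(),
            "",
            f"RMSD_bar(T) [whole molecule] = {self.rmsd_mean:.2f} A",
            (
                f"Predicted Tm = {self.prediction.tm:.1f} K "
                f"(reported: {self.prediction.tm_rounded} K)"
            ),
        ]
        if self.prediction.extrapolated:
            lines.append(
                "note: RMSD_bar(T) lies outside the calibration range "
                f"{self.prediction.calibration.rmsd_range}; "
                "prediction is an extrapolation"
            )
        return "\n".join(lines)


def run_md_tspc4(
    trajectories: Mapping[float, Trajectory],
    seq: IMotifSequence,
    calibration: TRCalibration | None = None,
    burn_in: float = 0.0,
) -> PipelineReport:
    """Run the MD-TSPC4 prediction pipeline on per-temperature trajectories.

    For every temperature: compute the whole-molecule best-fit RMSD
    series against the first frame and time-average it; also tabulate
    core- and loop-region averages for the report.  The per-temperature
    whole-molecule averages are combined into RMSD_bar(T) and passed
    through the calibration line (the published one by default).
    """
    if calibration is None:
        calibration = published_calibration()
    cal_temps = sorted({t for t in trajectories})
    if len(cal_temps) < 2:
        raise AnalysisError("need trajectories at >=2 temperatures")
    regions = assign_regions(seq)
    n_atoms_set = {traj.n_atoms for traj in trajectories.values()}
    if len(n_atoms_set) != 1:
        raise AnalysisError(
            f"inconsistent topologies across temperatures: atom counts {n_atoms_set}"
        )

    rows = {}
    for temp in cal_temps:
        traj = trajectories[temp]
        row = {}
        for region in ("whole", "core", "loop"):
            sel = select_atoms(
                traj.topology, AtomSelection(region=region), regions
            )
            series = rmsd_series(traj, sel)
            row[region] = time_average_rmsd(series, burn_in=burn_in)
        rows[temp] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "temperature_K"

    rmsd_mean = mean_rmsd_over_temperatures(table["whole"].to_numpy())
    prediction = predict_tm(rmsd_mean, calibration)
    return PipelineReport(
        sequence_name=seq.name,
        rmsd_table=table,
        rmsd_mean=rmsd_mean,
        prediction=prediction,
    )
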