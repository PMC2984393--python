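"""Observables: measured mass-isotopomer distributions and the chi-square score.

GC/MS reports, per fragment, the fractions m0, m1, ... of molecules carrying
0, 1, ... extra mass units.  Two observables are modelled: lactate secreted
into the medium (fragment covering carbons 1-3) and ribose from cellular RNA
(carbons 1-5).  RNA ribose is a mixture of material synthesised de novo
during the labelling window and pre-existing unlabelled ribonucleotides; the
pre-existing fraction is the "dilution" d, so the observed distribution is
d * (1,0,...) + (1-d) * simulated.  Goodness of fit is the standard
chi-square over fractions, chi2 = sum_i ((f_e_i - f_t_i) / sd_i)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import LabelTrajectory
from .network import DATA_DIR

__all__ = [
    "Observable",
    "MIDDataset",
    "FitScore",
    "OBSERVABLES",
    "apply_dilution",
    "chi_square",
    "predict_observables",
    "load_mid_dataset",
    "reference_dataset",
]

#: floor for published standard deviations rounded down to zero
SD_FLOOR = 1e-4


@dataclass(frozen=True)
class Observable:
    """A measured fragment: which pool it samples and which carbons."""

    name: str
    pool: str
    fragment_carbons: tuple[int, ...]
    diluted: bool = False           # True if a pre-existing unlabelled
                                    # fraction mixes into the measurement
    n_shifts: int | None = None     # mass shifts reported (m0..m_{n-1});
                                    # the model MID is renormalised over them


#: default observables of the experiment; ribose is reported as m0..m4
OBSERVABLES: dict[str, Observable] = {
    "lactate": Observable("lactate", "lac", (1, 2, 3)),
    "ribose": Observable("ribose", "rib", (1, 2, 3, 4, 5), diluted=True,
                         n_shifts=5),
}


@dataclass
class MIDDataset:
    """Measured mass-isotopomer fractions with standard deviations."""

    condition: str
    fractions: dict[str, np.ndarray]    # observable -> m0..mk
    sd: dict[str, np.ndarray]
    dilution: float | None = None       # known/reported dilution, if any

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            f = np.asarray(f, dtype=float)
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError(f"{name}: fractions outside [0, 1]")
            if abs(f.sum() - 1.0) > 0.02:
                raise ValueError(f"{name}: fractions sum to {f.sum():.4f}")
            # renormalise rounding slack in published tables
            self.fractions[name] = f / f.sum()
            s = np.asarray(self.sd[name], dtype=float)
            if np.any(s < 0):
                raise ValueError(f"{name}: negative sd")
            self.sd[name] = np.maximum(s, SD_FLOOR)


@dataclass
class FitScore:
    chi2: float
    contributions: dict[str, float] = field(default_factory=dict)
    residuals: dict[str, np.ndarray] = field(default_factory=dict)


def apply_dilution(mid_sim: np.ndarray, d: float) -> np.ndarray:
    """Mix a simulated MID with a pre-existing unlabelled fraction d."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("dilution must be within [0, 1]")
    mid_sim = np.asarray(mid_sim, dtype=float)
    out = (1.0 - d) * mid_sim
    out[0] += d
    return out


def chi_square(f_e, f_t, sd, name: str = "obs") -> FitScore:
    """chi2 = sum((f_e - f_t)^2 / sd^2) for one observable."""
    f_e = np.asarray(f_e, dtype=float)
    f_t = np.asarray(f_t, dtype=float)
    sd = np.maximum(np.asarray(sd, dtype=float), SD_FLOOR)
    if f_e.shape != f_t.shape or f_e.shape != sd.shape:
        raise ValueError("shape mismatch")
    res = (f_e - f_t) / sd
    return FitScore(float(res @ res), {name: float(res @ res)}, {name: res})


def score_dataset(dataset: MIDDataset, predicted: dict[str, np.ndarray]
                  ) -> FitScore:
    """Total chi-square of a dataset against predicted MIDs."""
    total = 0.0
    contributions: dict[str, float] = {}
    residuals: dict[str, np.ndarray] = {}
    for name, f_e in dataset.fractions.items():
        sc = chi_square(f_e, predicted[name], dataset.sd[name], name)
        total += sc.chi2
        contributions[name] = sc.chi2
        residuals[name] = sc.residuals[name]
    return FitScore(total, contributions, residuals)


def predict_observables(trajectory: LabelTrajectory, dilution: float = 0.0,
                        observables: dict[str, Observable] | None = None
                        ) -> dict[str, np.ndarray]:
    """MIDs of the measured observables at the end of the labelling window."""
    observables = observables or OBSERVABLES
    out: dict[str, np.ndarray] = {}
    for name, obs in observables.items():
        mid = trajectory.mid(obs.pool, list(obs.fragment_carbons))
        if obs.n_shifts is not None and obs.n_shifts < len(mid):
            mid = mid[:obs.n_shifts]
            mid = mid / mid.sum()
        if obs.diluted:
            mid = apply_dilution(mid, dilution)
        out[name] = mid
    return out


def optimal_dilution(mid_sim: np.ndarray, f_e: np.ndarray, sd: np.ndarray
                     ) -> float:
    """Weighted-least-squares dilution for one diluted observable.

    The observed MID is affine in d, so the chi-square-optimal d has the
    closed form of a 1-parameter linear fit; it is clipped into [0, 1].
    """
    e0 = np.zeros_like(mid_sim)
    e0[0] = 1.0
    direction = (e0 - mid_sim) / np.maximum(sd, SD_FLOOR)
    base = (mid_sim - f_e) / np.maximum(sd, SD_FLOOR)
    denom = direction @ direction
    if denom <= 0:
        return 0.0
    return float(np.clip(-(base @ direction) / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

def load_mid_dataset(path: str | Path, condition: str) -> MIDDataset:
    """Read a MID dataset from the TSV/CSV dialect used throughout.

    Columns: condition, metabolite, mass_shift, fraction, sd.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    df = df[df["condition"] == condition]
    if df.empty:
        raise KeyError(f"no rows for condition {condition!r}")
    fractions: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for met, grp in df.groupby("metabolite"):
        grp = grp.sort_values("mass_shift")
        fractions[met] = grp["fraction"].to_numpy(dtype=float)
        sds[met] = grp["sd"].to_numpy(dtype=float)
    return MIDDataset(condition, fractions, sds)


def reference_dataset(condition: str = "control",
                      column: str = "fraction") -> MIDDataset:
    """The packaged measured (or fitted, column='fit') distributions."""
    df = pd.read_csv(DATA_DIR / "mid_reference.tsv", sep="\t")
    df = df[df["condition"] == condition]
    meta = pd.read_csv(DATA_DIR / "mid_reference_meta.tsv",
                       sep="\t").set_index("condition")
    fractions: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for met, grp in df.groupby("metabolite"):
        grp = grp.sort_values("mass_shift")
        fractions[met] = grp[column].to_numpy(dtype=float)
        sds[met] = grp["sd"].to_numpy(dtype=float)
    return MIDDataset(condition, fractions, sds,
                      dilution=float(meta.loc[condition, "dilution"]))
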