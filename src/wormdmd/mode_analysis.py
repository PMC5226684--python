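"""Relating dynamic modes to the driven limit cycle, and cross-trial statistics.

The driven (PLM-stimulated) limit cycle defines three reference directions
in voltage space: the two dominant singular vectors of the mean-centered
cycle (the "plane modes" p1, p2 spanning the plane of oscillation) and the
unit "displacement mode" d pointing from the zero-input fixed point to the
cycle's center.  Each DMD mode phi is scored by |phi . d| and by
sqrt((phi.p1)^2 + (phi.p2)^2); a baseline comes from random unit vectors
(isotropic Gaussian, normalized).  Across an ensemble of impulse trials,
modes are matched by their timescale rank and summarized as box-plot
statistics (median, quartiles, whiskers, and the whisker spread
(Upper - Lower) / (2 * Median)).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmd import DMDResult

__all__ = [
    "PLMModes",
    "ModeEnsemble",
    "plm_modes",
    "displacement_projection",
    "plane_projection",
    "random_unit_mode",
    "aggregate_trials",
    "box_summary",
    "spread",
    "ks_compare",
]


@dataclass
class PLMModes:
    """Displacement mode d and orthonormal plane modes p1, p2 (all unit norm)."""

    d: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        for name in ("d", "p1", "p2"):
            vec = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, vec)
            if abs(np.linalg.norm(vec) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be unit length")
        if abs(self.p1 @ self.p2) > 1e-10:
            raise ValueError("plane modes must be orthogonal")


def plm_modes(cycle_trace, fixed_point: np.ndarray,
              planarity_floor: float = 1e-8) -> PLMModes:
    """Reference modes from a driven limit-cycle trace.

    The cycle center is the temporal mean of the trace; p1, p2 are the top
    two left singular vectors of the mean-centered trace, and d is the unit
    vector from ``fixed_point`` to the center.  The trace should cover at
    least two cycle periods past transient so the temporal mean estimates
    the cycle center.
    """
    V = cycle_trace.V
    center = V.mean(axis=1)
    Xc = V - center[:, None]
    U, sigma, _ = np.linalg.svd(Xc, full_matrices=False)
    if sigma.size < 2 or sigma[1] <= planarity_floor * sigma[0]:
        raise ValueError("cycle not planar: second singular value below floor")
    disp = center - np.asarray(fixed_point, dtype=float)
    norm = np.linalg.norm(disp)
    if norm <= planarity_floor * max(1.0, np.linalg.norm(center)):
        raise ValueError("cycle centered at the fixed point: zero displacement mode")
    return PLMModes(d=disp / norm, p1=U[:, 0], p2=U[:, 1])


def displacement_projection(phi: np.ndarray, modes: PLMModes) -> float:
    """Magnitude of the mode's projection onto the displacement mode, |phi . d|."""
    return float(np.abs(np.asarray(phi).conj() @ modes.d))


def plane_projection(phi: np.ndarray, modes: PLMModes) -> float:
    """In-plane projection magnitude sqrt((phi.p1)^2 + (phi.p2)^2)."""
    phi = np.asarray(phi)
    a = np.abs(phi.conj() @ modes.p1)
    b = np.abs(phi.conj() @ modes.p2)
    return float(np.hypot(a, b))


def random_unit_mode(n: int, seed=None) -> np.ndarray:
    """Isotropic random unit vector: i.i.d. Gaussian entries, normalized."""
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal(n)
    return vec / np.linalg.norm(vec)


def spread(upper: float, lower: float, median: float) -> float:
    """Whisker spread (Upper - Lower) / (2 * Median) of a box summary."""
    return (upper - lower) / (2.0 * median)


def box_summary(samples: np.ndarray, whiskers: str = "tukey") -> dict[str, float]:
    """Box-plot statistics of a 1-D sample.

    ``whiskers="tukey"`` places whiskers at the most extreme observations
    within 1.5 IQR of the quartiles (the MATLAB/matplotlib boxplot
    default); ``whiskers="minmax"`` uses the sample extremes (no points
    treated as outliers).
    """
    x = np.asarray(samples, dtype=float)
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    if whiskers == "tukey":
        iqr = q75 - q25
        lo = x[x >= q25 - 1.5 * iqr].min()
        hi = x[x <= q75 + 1.5 * iqr].max()
    elif whiskers == "minmax":
        lo, hi = x.min(), x.max()
    else:
        raise ValueError(f"unknown whisker convention {whiskers!r}")
    return {"Upper": hi, "75th": q75, "Median": med, "25th": q25, "Lower": lo,
            "Spread": spread(hi, lo, med)}


@dataclass
class ModeEnsemble:
    """Per-timescale-rank distributions of tau and projections across trials.

    Rows of each array are trials, columns are mode indices 1..r ordered by
    ascending timescale (index 1 = fastest decay).  Trials whose mode count
    deviated from the ensemble's modal count are excluded and counted in
    ``n_excluded``.
    """

    taus: np.ndarray          # (n_trials, r) seconds
    disp: np.ndarray          # (n_trials, r)
    plane: np.ndarray         # (n_trials, r)
    n_excluded: int = 0

    @property
    def r(self) -> int:
        return self.taus.shape[1]

    @property
    def n_trials(self) -> int:
        return self.taus.shape[0]

    def summary(self, which: str = "tau", whiskers: str = "tukey") -> pd.DataFrame:
        """Box statistics per mode index, in table order
        (Upper, 75th, Median, 25th, Lower, Spread)."""
        data = {"tau": self.taus, "disp": self.disp, "plane": self.plane}[which]
        rows = [box_summary(data[:, j], whiskers) for j in range(self.r)]
        return pd.DataFrame(rows, index=[f"Mode {j + 1}" for j in range(self.r)])


def aggregate_trials(results: list[DMDResult], modes: PLMModes) -> ModeEnsemble:
    """Collect per-mode statistics across impulse trials.

    Within each trial, modes are sorted by ascending timescale and matched
    across trials by rank (the only correspondence the mode labels
    support).  Trials whose retained mode count differs from the majority
    are excluded from the per-index statistics with a warning.
    """
    if not results:
        raise ValueError("no DMD results to aggregate")
    counts = Counter(res.eigenvalues.size for res in results)
    r_modal = counts.most_common(1)[0][0]
    kept = [res for res in results if res.eigenvalues.size == r_modal]
    n_excluded = len(results) - len(kept)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} trial(s) with mode count != {r_modal} excluded from summary"
        )
    taus = np.empty((len(kept), r_modal))
    disp = np.empty_like(taus)
    plane = np.empty_like(taus)
    for t, res in enumerate(kept):
        order = np.argsort(res.taus.real)
        taus[t] = res.taus.real[order]
        for j, col in enumerate(order):
            phi = res.modes[:, col]
            disp[t, j] = displacement_projection(phi, modes)
            plane[t, j] = plane_projection(phi, modes)
    return ModeEnsemble(taus, disp, plane, n_excluded)


def ks_compare(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov p-value (null: same distribution)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.ks_2samp(a, b).pvalue)
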