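"""Planar limit-cycle extraction and Procrustes shape comparison.

Trajectories are projected onto the two plane modes of the reference
(driven) limit cycle, a single period is cut out after discarding the
transient, resampled to a common number of points by periodic splines, and
compared by the normalized Procrustes dissimilarity: the residual sum of
squares after the optimal translation, rotation (reflection allowed by
default) and positive scaling, normalized so the value is scale-free and
lies in [0, 1].  Phase alignment minimizes the distance over all cyclic
shifts of the point ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "PlanarCycle",
    "project_plane",
    "extract_period",
    "resample_cycle",
    "procrustes_distance",
    "phase_align",
    "ablation_scan",
    "NoCycleError",
]


class NoCycleError(RuntimeError):
    """Raised when no periodic component can be detected in a trajectory."""


@dataclass
class PlanarCycle:
    """One closed period of a planar trajectory: 2 x N points plus duration."""

    points: np.ndarray    # (2, N)
    period: float         # s

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] != 2:
            raise ValueError("points must be a 2 x N matrix")
        if self.points.shape[1] < 16:
            raise ValueError("a cycle needs at least 16 points; sample finer")

    @property
    def N(self) -> int:
        return self.points.shape[1]


def project_plane(trace, modes) -> np.ndarray:
    """Project a voltage trace onto the plane modes.

    Returns a 2 x m trajectory: row 1 is (v(t) - vbar) . p1 and row 2 is
    (v(t) - vbar) . p2, with vbar the temporal mean of the trace.
    """
    Xc = trace.V - trace.V.mean(axis=1, keepdims=True)
    return np.vstack([modes.p1 @ Xc, modes.p2 @ Xc])


def extract_period(traj: np.ndarray, dt: float,
                   transient_fraction: float = 0.5,
                   peak_floor: float = 0.2) -> PlanarCycle:
    """Cut one period out of a planar trajectory.

    The first ``transient_fraction`` of the samples is discarded; the
    period is the lag of the dominant autocorrelation peak of the first
    coordinate, and the returned cycle starts at a positive-going crossing
    of that coordinate's mean.  Raises :class:`NoCycleError` when no
    autocorrelation peak exceeds ``peak_floor``.
    """
    traj = np.asarray(traj, dtype=float)
    start = int(round(transient_fraction * traj.shape[1]))
    seg = traj[:, start:]
    x = seg[0] - seg[0].mean()
    denom = x @ x
    if denom <= 0:
        raise NoCycleError("no periodic component: trajectory is constant")
    # unbiased autocorrelation (divide by overlap, not length): the raw
    # estimator shrinks with lag and drags the peak toward shorter periods
    m = x.size
    raw = np.correlate(x, x, mode="full")[m:]
    lags = np.arange(1, m)
    ac = raw * m / ((m - lags) * denom)
    ac = np.concatenate([[1.0], ac[: m // 2]])  # longer lags: too little overlap
    # search for the dominant peak past the first minimum (the unbiased
    # overlap correction inflates tiny lags above 1); pad the end so a
    # peak at exactly half the segment is still detectable
    mins, _ = find_peaks(-ac)
    if mins.size == 0:
        raise NoCycleError("no periodic component: autocorrelation never dips")
    padded = np.concatenate([ac, [-np.inf]])
    peaks, _ = find_peaks(padded)
    peaks = peaks[(peaks > mins[0]) & (padded[peaks] > peak_floor)]
    if peaks.size == 0:
        raise NoCycleError("no periodic component: autocorrelation peak below floor")
    coarse = int(peaks[np.argmax(ac[peaks])])
    if seg.shape[1] < 2 * coarse:
        raise NoCycleError("post-transient segment shorter than two periods")

    # refine to sub-sample accuracy from the spacing of positive-going
    # mean crossings (the coarse peak carries an O(1)-sample bias when the
    # segment holds a non-integer number of periods); crossings closer
    # than half a coarse period are harmonics, not new cycles
    whole = (m // coarse) * coarse
    mu = seg[0, :whole].mean()
    y = seg[0] - mu
    idx = np.flatnonzero((y[:-1] <= 0) & (y[1:] > 0))
    pos = idx + y[idx] / (y[idx] - y[idx + 1])
    if pos.size >= 2:
        keep = [pos[0]]
        for p in pos[1:]:
            if p - keep[-1] > 0.5 * coarse:
                keep.append(p)
        if len(keep) >= 2:
            period_samples = (keep[-1] - keep[0]) / (len(keep) - 1)
        else:
            period_samples = float(coarse)
    else:
        period_samples = float(coarse)
    lag = int(round(period_samples))
    i0 = int(np.ceil(pos[0])) if pos.size else 0
    if i0 + lag > seg.shape[1]:
        i0 = 0
    return PlanarCycle(seg[:, i0:i0 + lag], period=period_samples * dt)


def resample_cycle(cycle: PlanarCycle, N: int = 200) -> PlanarCycle:
    """Resample a cycle at N uniform phase points by periodic cubic splines."""
    if N < 16:
        raise ValueError("need at least 16 resampled points")
    pts = cycle.points
    phases_in = np.linspace(0.0, 1.0, pts.shape[1] + 1)
    closed = np.column_stack([pts, pts[:, 0]])
    spline = CubicSpline(phases_in, closed.T, bc_type="periodic")
    phases_out = np.arange(N) / N
    return PlanarCycle(spline(phases_out).T, period=cycle.period)


def _standardize(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered)
    return centered, norm


def procrustes_distance(a: PlanarCycle, b: PlanarCycle,
                        allow_reflection: bool = True) -> float:
    """Normalized Procrustes dissimilarity between two equal-N cycles.

    Minimizes ||S_b - b R S_a - c||^2 over translation c, positive scale b
    and 2-D rotation R (optionally including reflections), normalized by
    the centered sum of squares so the value is scale-free:
    d = 1 - (sum of Procrustes singular values)^2 / (||A|| ||B||)^2,
    which is 0 iff the shapes are similarity-equivalent.
    """
    if a.N != b.N:
        raise ValueError("cycles must have equal point counts; resample first")
    A, na = _standardize(a.points)
    B, nb = _standardize(b.points)
    if na == 0 or nb == 0:
        raise ValueError("degenerate shape: all points identical")
    U, s, Vt = np.linalg.svd(A @ B.T)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        # restrict to proper rotations: flip the smallest singular value
        s = s.copy()
        s[-1] = -s[-1]
    d = 1.0 - (s.sum() / (na * nb)) ** 2
    return float(max(d, 0.0))


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def orient_ccw(cycle: PlanarCycle) -> PlanarCycle:
    """Normalize traversal to counterclockwise (positive signed area)."""
    if _signed_area(cycle.points) < 0:
        return PlanarCycle(cycle.points[:, ::-1].copy(), cycle.period)
    return cycle


def phase_align(a: PlanarCycle, b: PlanarCycle) -> tuple[int, float]:
    """Best cyclic shift of ``a``'s point ordering against ``b``.

    Both cycles are first oriented counterclockwise (traversal orientation
    preserved during the shift search); returns (argmin shift, minimum
    Procrustes distance over all N shifts).
    """
    if a.N != b.N:
        raise ValueError("cycles must have equal point counts; resample first")
    a = orient_ccw(a)
    b = orient_ccw(b)
    best_shift, best_d = 0, np.inf
    for shift in range(a.N):
        shifted = PlanarCycle(np.roll(a.points, -shift, axis=1), a.period)
        d = procrustes_distance(shifted, b)
        if d < best_d:
            best_shift, best_d = shift, d
    return best_shift, float(best_d)


def ablation_scan(c, ablation_sets: dict, drive_params: dict,
                  reference: PlanarCycle, modes, params, *,
                  T: float = 2.0, h: float = 1e-5, dt_record: float = 1e-3,
                  transient_fraction: float = 0.5, N: int = 200,
                  initial=None) -> pd.DataFrame:
    """Cycle distortion under simulated ablations.

    For each named neuron set, the ablated network is driven with the same
    traveling-wave input, its plane-projected cycle is extracted, resampled
    and phase-aligned against the unablated reference, and the Procrustes
    distance is reported.  Networks with no periodic response get a NaN
    distance and a "no-cycle" note.  Rows are sorted by descending
    distortion.
    """
    from .connectome import ablate, conductance_matrices
    from .dynamics import find_fixed_point, integrate, proprioceptive_drive

    ref = resample_cycle(reference, N) if reference.N != N else reference
    rows = []
    for name, names in ablation_sets.items():
        cab = ablate(c, names)
        cond = conductance_matrices(cab, params.g)
        stim = proprioceptive_drive(cab, **drive_params)
        try:
            start = initial if initial is not None else find_fixed_point(cond, params)
            trace = integrate(start, cond, params, stim, T=T, h=h,
                              dt_record=dt_record)
            traj = project_plane(trace, modes)
            cyc = extract_period(traj, dt_record, transient_fraction)
            cyc = resample_cycle(cyc, N)
            _, dist = phase_align(cyc, ref)
            rows.append({"set": name, "distance": dist, "note": ""})
        except NoCycleError as err:
            rows.append({"set": name, "distance": np.nan, "note": f"no-cycle: {err}"})
    df = pd.DataFrame(rows).sort_values(
        "distance", ascending=False, na_position="last").reset_index(drop=True)
    return df
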