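"""Exact dynamic mode decomposition of voltage traces.

Snapshot pairs (X, X') are related by a best-fit linear operator
A = X' pinv(X); the pseudoinverse is formed from a singular value
decomposition truncated at the smallest rank whose cumulative energy
reaches a threshold (default 99%).  Eigenpairs of the reduced r x r
operator give the DMD eigenvalues; projecting each reduced eigenvector
back through X' V Sigma^-1 gives the full-dimensional dynamic modes.
Each eigenvalue maps to a continuous timescale via
lambda = exp(-dt / tau).

The "energy" captured by a singular value is, by default, its share of
the singular-value *sum* (sigma semantics); ``energy="sigma2"`` selects
the squared-singular-value (variance) convention instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DMDResult",
    "snapshot_matrices",
    "exact_dmd",
    "decay_constants",
    "fit_amplitudes",
    "reconstruct",
]


@dataclass
class DMDResult:
    """Modes, eigenvalues, timescales and amplitudes of one decomposition.

    ``modes`` columns are unit-norm dynamic modes (sign/phase fixed by
    making the largest-magnitude entry real-positive); ``taus`` satisfy
    ``eigenvalues = exp(-dt / taus)``.  Entries are ordered from fastest
    to slowest decay (ascending |eigenvalue|).  ``amplitudes`` is None
    until :func:`fit_amplitudes` is called.
    """

    modes: np.ndarray             # (n, r)
    eigenvalues: np.ndarray       # (r,) complex
    taus: np.ndarray              # (r,) complex, seconds
    singular_values: np.ndarray   # retained sigmas
    rank: int
    energy_threshold: float
    dt: float
    amplitudes: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.modes.shape[0]


def snapshot_matrices(trace) -> tuple[np.ndarray, np.ndarray]:
    """Split a voltage trace into the time-shifted snapshot pair (X, X')."""
    V = trace.V
    if V.shape[1] < 3:
        raise ValueError("need at least 3 recorded columns for snapshot pairs")
    return V[:, :-1], V[:, 1:]


def _energy_rank(sigma: np.ndarray, threshold: float, energy: str) -> int:
    if energy == "sigma":
        w = sigma
    elif energy == "sigma2":
        w = sigma**2
    else:
        raise ValueError(f"unknown energy semantics {energy!r}")
    frac = np.cumsum(w) / w.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def exact_dmd(X: np.ndarray, Xp: np.ndarray, energy_threshold: float = 0.99,
              dt: float = 3e-5, energy: str = "sigma",
              sigma_floor: float = 1e-12) -> DMDResult:
    """Dynamic mode decomposition of the snapshot pair at an energy threshold.

    Parameters
    ----------
    X, Xp : (n, m-1) arrays
        Time-shifted snapshot matrices.
    energy_threshold : float
        Retain the smallest r singular values capturing this fraction of
        the energy.
    dt : float
        Snapshot spacing in seconds (sets the timescales).
    energy : {"sigma", "sigma2"}
        Whether energy fractions are computed from sigma or sigma^2.
    sigma_floor : float
        Singular values below ``sigma_floor * sigma_max`` are treated as
        numerical noise and dropped before thresholding.
    """
    if X.shape != Xp.shape:
        raise ValueError("X and X' must have identical shapes")
    if not 0.0 < energy_threshold <= 1.0:
        raise ValueError("energy_threshold must lie in (0, 1]")
    U, sigma, Vh = np.linalg.svd(X, full_matrices=False)
    if sigma.size == 0 or sigma[0] == 0.0:
        raise ValueError("all-zero snapshot matrix")
    keep = sigma > sigma_floor * sigma[0]
    U, sigma, Vh = U[:, keep], sigma[keep], Vh[keep]

    r = _energy_rank(sigma, energy_threshold, energy)
    U, sigma, Vh = U[:, :r], sigma[:r], Vh[:r]

    B = Xp @ Vh.conj().T / sigma          # X' V Sigma^-1, reused for modes
    A_tilde = U.conj().T @ B
    lam, W = np.linalg.eig(A_tilde)

    nonzero = np.abs(lam) > 1e-14
    if not nonzero.all():
        warnings.warn("zero DMD eigenvalues excluded from mode projection")
    lam, W = lam[nonzero], W[:, nonzero]

    modes = B @ W
    # normalize and fix phase: largest-magnitude entry real-positive
    norms = np.linalg.norm(modes, axis=0)
    norms[norms == 0] = 1.0
    modes = modes / norms
    lead = np.argmax(np.abs(modes), axis=0)
    ref = modes[lead, np.arange(modes.shape[1])]
    phase = ref / np.abs(ref)
    modes = modes / phase

    order = np.argsort(np.abs(lam))        # fastest decay first
    lam, modes = lam[order], modes[:, order]
    if np.isrealobj(X) and np.allclose(modes.imag, 0, atol=1e-12):
        modes = modes.real
    taus = decay_constants(lam, dt)
    return DMDResult(modes=modes, eigenvalues=lam, taus=taus,
                     singular_values=sigma, rank=r,
                     energy_threshold=energy_threshold, dt=dt)


def decay_constants(eigenvalues: np.ndarray, dt: float) -> np.ndarray:
    """Continuous timescales tau = -dt / ln(lambda).

    Real eigenvalues in (0, 1) give real positive decay constants;
    lambda = 1 maps to an infinite timescale (flagged, not an error).
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    if (np.abs(lam) < 1e-300).any():
        raise ValueError("zero eigenvalue has no finite timescale; filter upstream")
    taus = np.empty_like(lam)
    unit = lam == 1.0
    if unit.any():
        warnings.warn("eigenvalue exactly 1: infinite timescale")
    taus[unit] = np.inf
    taus[~unit] = -dt / np.log(lam[~unit])
    return taus


def fit_amplitudes(result: DMDResult, v0: np.ndarray) -> np.ndarray:
    """Least-squares mode amplitudes of an initial state: v0 ~ sum c_j phi_j.

    Stores the coefficients on ``result`` and returns them; a
    rank-deficient mode matrix degrades gracefully to the minimum-norm
    solution with a warning.
    """
    c, _, rank, _ = np.linalg.lstsq(result.modes, np.asarray(v0, dtype=complex))
    if rank < result.modes.shape[1]:
        warnings.warn("rank-deficient mode matrix: minimum-norm amplitudes")
    result.amplitudes = c
    return c


def reconstruct(result: DMDResult, t: float) -> np.ndarray:
    """State at time t from the fitted expansion sum_j c_j phi_j exp(-t/tau_j).

    At recorded times t = k*dt this equals the discrete power form
    sum_j c_j lambda_j^k phi_j to round-off.  Returns the real part.
    """
    if result.amplitudes is None:
        raise ValueError("call fit_amplitudes first")
    with np.errstate(divide="ignore"):
        decay = np.where(np.isinf(result.taus), 1.0, np.exp(-t / result.taus))
    return np.real(result.modes @ (result.amplitudes * decay))
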