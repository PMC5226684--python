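"""Single-compartment membrane dynamics on the connectome.

Each neuron i carries a membrane voltage v_i (mV) and a graded synaptic
activity s_i in [0, 1]:

    C dv_i/dt = -Gc (v_i - Ecell) - sum_j Gg_ij (v_i - v_j)
                - sum_j Gs_ij s_j (v_i - E_j) + I_ext_i
    ds_i/dt   = ar * phi(v_i) * (1 - s_i) - ad * s_i

with phi the logistic sigmoid phi(v) = 1 / (1 + exp(-beta (v - vth))) and
E_j the excitatory or inhibitory reversal potential of the *presynaptic*
neuron.  Units: pF, pS, mV, s — with these, pS/pF = 1/s so voltages in mV
integrate consistently against time in seconds, and "current" means pS*mV
model units throughout.

Per-neuron thresholds vth are chosen so that the zero-input network
equilibrium sits exactly at threshold (phi = 1/2), obtained by one linear
solve; this is the conventional calibration for this model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import expit

from .connectome import Connectome, ConductancePair, bclass_members, conductance_matrices

__all__ = [
    "ModelParams",
    "NetworkState",
    "Stimulus",
    "VoltageTrace",
    "sigmoid",
    "synaptic_equilibrium",
    "solve_thresholds",
    "vector_field",
    "find_fixed_point",
    "integrate",
    "random_impulse",
    "proprioceptive_drive",
    "plm_drive",
    "SimulationBlowupError",
    "FixedPointError",
]


class SimulationBlowupError(RuntimeError):
    """Raised when the integrated state diverges or turns non-finite."""


class FixedPointError(RuntimeError):
    """Raised when the fixed-point solver fails to converge."""


@dataclass
class ModelParams:
    """Biophysical constants of the membrane/synapse model.

    Defaults: C = 1 pF, Gc = 10 pS (leak time constant 0.1 s), per-contact
    conductance g = 100 pS, synaptic rise ar = 1/s and decay ad = 5/s.
    The leak reversal Ecell = -35 mV, synaptic reversals E_exc = 0 mV /
    E_inh = -45 mV and sigmoid slope beta = 0.125 / mV follow the
    established convention for this model family.  ``vth`` is the
    per-neuron threshold vector; leave None to have it solved from the
    network's zero-input equilibrium (see :func:`solve_thresholds`).
    """

    C: float = 1.0            # pF
    Gc: float = 10.0          # pS
    Ecell: float = -35.0      # mV
    g: float = 100.0          # pS per contact
    ar: float = 1.0           # 1/s
    ad: float = 5.0           # 1/s
    beta: float = 0.125       # 1/mV
    E_exc: float = 0.0        # mV
    E_inh: float = -45.0      # mV
    vth: np.ndarray | None = None  # mV, per neuron

    def __post_init__(self):
        if self.C <= 0 or self.g <= 0 or self.ar <= 0 or self.ad <= 0:
            raise ValueError("C, g, ar, ad must be positive")
        if self.Gc < 0 or self.beta < 0:
            raise ValueError("Gc and beta must be nonnegative")

    def reversal_vector(self, excitatory: np.ndarray) -> np.ndarray:
        """Per-presynaptic-neuron reversal potential E_j (mV)."""
        return np.where(excitatory, self.E_exc, self.E_inh)

    def with_thresholds(self, cond: ConductancePair) -> "ModelParams":
        """Return a copy with ``vth`` solved from the zero-input equilibrium."""
        return replace(self, vth=solve_thresholds(cond, self))


@dataclass
class NetworkState:
    """Instantaneous network state: voltages (mV) and synaptic activities."""

    v: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.v.shape != self.s.shape:
            raise ValueError("v and s must have equal length")

    def copy(self) -> "NetworkState":
        return NetworkState(self.v.copy(), self.s.copy())


@dataclass
class Stimulus:
    """Time-dependent external current I_ext(t), in model current units.

    ``current(t)`` returns the per-neuron input vector; impulse-type
    stimuli return zeros outside [0, duration).
    """

    kind: str
    n: int
    duration: float
    _fn: Callable[[float], np.ndarray]
    params: dict = field(default_factory=dict)

    def current(self, t: float) -> np.ndarray:
        return self._fn(t)

    @classmethod
    def none(cls, n: int) -> "Stimulus":
        zero = np.zeros(n)
        return cls("none", n, np.inf, lambda t: zero)

    @classmethod
    def constant(cls, vec: np.ndarray, kind: str = "constant",
                 params: dict | None = None) -> "Stimulus":
        vec = np.asarray(vec, dtype=float)
        return cls(kind, len(vec), np.inf, lambda t: vec, params or {})


@dataclass
class VoltageTrace:
    """Recorded voltage matrix: column k holds v(t0 + k * dt_record)."""

    V: np.ndarray          # (n, m) mV
    dt_record: float       # s
    t0: float = 0.0        # s

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[1] < 2:
            raise ValueError("trace needs at least two recorded columns")
        if self.dt_record <= 0:
            raise ValueError("dt_record must be positive")

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def m(self) -> int:
        return self.V.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt_record * np.arange(self.m)


# ---------------------------------------------------------------------------
# model right-hand side
# ---------------------------------------------------------------------------

def sigmoid(v, beta: float, vth) -> np.ndarray:
    """Logistic activation phi(v) = 1/(1 + exp(-beta (v - vth))), overflow-safe."""
    return expit(beta * (np.asarray(v, dtype=float) - vth))


def synaptic_equilibrium(v, params: ModelParams, vth=None) -> np.ndarray:
    """Steady-state synaptic activity s_eq = ar phi / (ar phi + ad)."""
    if vth is None:
        vth = params.vth if params.vth is not None else 0.0
    phi = sigmoid(v, params.beta, vth)
    return params.ar * phi / (params.ar * phi + params.ad)


def vector_field(state: NetworkState, cond: ConductancePair, params: ModelParams,
                 I_ext=None) -> NetworkState:
    """Time derivative (dv/dt, ds/dt) of the model at the given state."""
    v, s = state.v, state.s
    if not (np.isfinite(v).all() and np.isfinite(s).all()):
        raise SimulationBlowupError("non-finite state passed to vector_field")
    if params.vth is None:
        raise ValueError("params.vth unset; call params.with_thresholds(cond) first")
    E = params.reversal_vector(cond.excitatory)
    I_gap = cond.G_gap.sum(axis=1) * v - cond.G_gap @ v
    I_syn = (cond.G_syn @ s) * v - cond.G_syn @ (s * E)
    ext = 0.0 if I_ext is None else I_ext
    vdot = (-params.Gc * (v - params.Ecell) - I_gap - I_syn + ext) / params.C
    phi = sigmoid(v, params.beta, params.vth)
    sdot = params.ar * phi * (1.0 - s) - params.ad * s
    return NetworkState(vdot, sdot)


def gap_currents(state: NetworkState, cond: ConductancePair) -> np.ndarray:
    """Per-neuron gap-junction current; sums to zero over the network."""
    v = state.v
    return cond.G_gap.sum(axis=1) * v - cond.G_gap @ v


# ---------------------------------------------------------------------------
# thresholds and fixed point
# ---------------------------------------------------------------------------

def solve_thresholds(cond: ConductancePair, params: ModelParams) -> np.ndarray:
    """Per-neuron thresholds putting the zero-input equilibrium at phi = 1/2.

    With phi pinned at 1/2 the synaptic activities equal
    s* = ar/2 / (ar/2 + ad) and the voltage equation becomes linear; its
    solution v* is taken as the threshold vector, which makes (v*, s*) an
    exact zero-input fixed point of the full nonlinear system.
    """
    n = cond.n
    s_half = 0.5 * params.ar / (0.5 * params.ar + params.ad)
    E = params.reversal_vector(cond.excitatory)
    L_gap = np.diag(cond.G_gap.sum(axis=1)) - cond.G_gap
    syn_in = cond.G_syn.sum(axis=1)
    M = params.Gc * np.eye(n) + L_gap + s_half * np.diag(syn_in)
    b = params.Gc * params.Ecell * np.ones(n) + s_half * (cond.G_syn @ E)
    return np.linalg.solve(M, b)


def find_fixed_point(cond: ConductancePair, params: ModelParams, I_ext=None,
                     v0=None, tol: float = 1e-9, max_iter: int = 200) -> NetworkState:
    """Solve the network fixed point by damped Newton on the voltage subsystem.

    Substituting s = s_eq(v) reduces the 2n-dimensional root problem to n
    dimensions; Newton steps are damped by backtracking on the residual
    norm, with a long-integration fallback before giving up.  The returned
    state satisfies ``max |vector_field| < tol`` (model units) and has
    ``s`` exactly at its voltage-conditional equilibrium.
    """
    if params.vth is None:
        raise ValueError("params.vth unset; call params.with_thresholds(cond) first")
    n = cond.n
    E = params.reversal_vector(cond.excitatory)
    L_gap = np.diag(cond.G_gap.sum(axis=1)) - cond.G_gap
    ext = np.zeros(n) if I_ext is None else np.asarray(I_ext, dtype=float)

    def residual(v):
        s = synaptic_equilibrium(v, params)
        return (-params.Gc * (v - params.Ecell) - L_gap @ v
                - (cond.G_syn @ s) * v + cond.G_syn @ (s * E) + ext)

    def jacobian(v):
        phi = sigmoid(v, params.beta, params.vth)
        s = params.ar * phi / (params.ar * phi + params.ad)
        # ds_eq/dv = ar ad beta phi(1-phi) / (ar phi + ad)^2
        dsdv = (params.ar * params.ad * params.beta * phi * (1 - phi)
                / (params.ar * phi + params.ad) ** 2)
        J = -params.Gc * np.eye(n) - L_gap
        J -= np.diag(cond.G_syn @ s)
        J += (cond.G_syn * (E - v[:, None])) * dsdv[None, :]
        return J

    v = np.array(params.vth if v0 is None else v0, dtype=float)
    for attempt in range(2):
        for _ in range(max_iter):
            F = residual(v)
            if np.max(np.abs(F)) < tol:
                state = NetworkState(v, synaptic_equilibrium(v, params))
                return state
            step = np.linalg.solve(jacobian(v), -F)
            lam, f0 = 1.0, np.linalg.norm(F)
            for _ in range(40):
                if np.linalg.norm(residual(v + lam * step)) < f0:
                    break
                lam *= 0.5
            v = v + lam * step
        if attempt == 0:
            # relaxation fallback: integrate toward the attractor, retry Newton
            state = NetworkState(v, synaptic_equilibrium(v, params))
            trace = integrate(state, cond, params, Stimulus.none(n),
                              T=2.0, h=1e-4, dt_record=1e-2)
            v = trace.V[:, -1]
    raise FixedPointError(
        "fixed-point iteration did not converge; consider a damped/continuation "
        "start from the threshold solution or a longer relaxation integration"
    )


# ---------------------------------------------------------------------------
# forward-Euler integration with downsampled recording
# ---------------------------------------------------------------------------

def integrate(initial: NetworkState, cond: ConductancePair, params: ModelParams,
              stim: Stimulus, T: float, h: float = 1e-6,
              dt_record: float = 3e-5, record_start: float = 0.0,
              v_bound: float = 1e4) -> VoltageTrace:
    """Explicit Euler integration, recording v every ``dt_record`` seconds.

    ``dt_record`` must be an integer multiple of the step ``h`` (the model
    default h = 1e-6 s with dt_record = 3e-5 s records every 30th step).
    Recording starts at ``record_start`` (e.g. just after an impulse ends);
    the first recorded column is the state at that time.  Voltages
    exceeding ``v_bound`` in magnitude abort with the blow-up time.
    """
    if params.vth is None:
        raise ValueError("params.vth unset; call params.with_thresholds(cond) first")
    every = dt_record / h
    if abs(every - round(every)) > 1e-6 * every:
        raise ValueError("dt_record must be an integer multiple of h")
    every = int(round(every))
    if T <= dt_record:
        raise ValueError("T must exceed dt_record")

    n = cond.n
    E = params.reversal_vector(cond.excitatory)
    gap_deg = cond.G_gap.sum(axis=1)
    G_syn_E = cond.G_syn * E[None, :]
    Gc, C, Ecell = params.Gc, params.C, params.Ecell
    ar, ad, beta, vth = params.ar, params.ad, params.beta, params.vth

    n_steps = int(round(T / h))
    start_step = int(round(record_start / h))
    m = (n_steps - start_step) // every + 1
    if m < 2:
        raise ValueError("recording window too short for two columns")
    V = np.empty((n, m))

    v = initial.v.copy()
    s = np.clip(initial.s.copy(), 0.0, 1.0)
    col = 0
    finite_stim = np.isfinite(stim.duration)
    for k in range(n_steps + 1):
        t = k * h
        if k >= start_step and (k - start_step) % every == 0 and col < m:
            V[:, col] = v
            col += 1
        if k == n_steps:
            break
        I = stim.current(t) if (not finite_stim or t < stim.duration) else None
        I_gap = gap_deg * v - cond.G_gap @ v
        I_syn = (cond.G_syn @ s) * v - G_syn_E @ s
        vdot = (-Gc * (v - Ecell) - I_gap - I_syn) / C
        if I is not None:
            vdot = vdot + I / C
        phi = expit(beta * (v - vth))
        sdot = ar * phi * (1.0 - s) - ad * s
        v = v + h * vdot
        s = np.clip(s + h * sdot, 0.0, 1.0)
        if k % every == 0:
            vmax = np.max(np.abs(v))
            if not np.isfinite(vmax) or vmax > v_bound:
                raise SimulationBlowupError(f"voltage blow-up at t = {t + h:.6g} s")
    return VoltageTrace(V[:, :col], dt_record, t0=start_step * h)


# ---------------------------------------------------------------------------
# stimulus protocols
# ---------------------------------------------------------------------------

def random_impulse(n: int, seed, amplitude: float = 10.0,
                   duration: float = 1e-5) -> Stimulus:
    """Brief random kick into every neuron.

    Per-neuron currents are drawn i.i.d. Gaussian then rescaled so the
    Euclidean norm of the input vector equals ``amplitude`` (default 10
    model current units); the input is constant during [0, duration)
    (default 10 microseconds) and zero afterwards.
    """
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal(n)
    vec *= amplitude / np.linalg.norm(vec)
    zero = np.zeros(n)

    def fn(t):
        return vec if 0.0 <= t < duration else zero

    return Stimulus("random_impulse", n, duration, fn,
                    {"amplitude": amplitude, "seed": seed})


def proprioceptive_drive(c: Connectome, A: float = 30.0, omega: float = 25.0,
                         k: float = 0.886, dorsal_sign: float = -1.0) -> Stimulus:
    """Traveling sinusoidal input into B-class motorneurons.

    I_i(t) = sigma_i * A * sin(omega t - 2 pi k x_i) for B-class neurons,
    zero elsewhere, where x_i is the normalized soma position, k the
    spatial wavenumber in cycles per body length (wavelength 1/k body
    lengths) and sigma_i = +1 for ventral, -1 for dorsal cells (the
    opposite orientation only shifts the drive phase by pi and is
    selectable via ``dorsal_sign``).
    """
    members = bclass_members(c)
    if not members:
        raise ValueError("connectome has no B-class motorneurons")
    idx = c.index(members)
    x = c.soma_pos[idx]
    dv = c.dv_label[idx]
    if np.isnan(x).any():
        bad = [members[i] for i in np.flatnonzero(np.isnan(x))]
        raise ValueError(f"B-class neurons missing soma positions: {bad}")
    if any(lbl not in ("dorsal", "ventral") for lbl in dv):
        bad = [m for m, lbl in zip(members, dv) if lbl not in ("dorsal", "ventral")]
        raise ValueError(f"B-class neurons missing dorsal/ventral labels: {bad}")
    sign = np.where(dv == "ventral", -dorsal_sign, dorsal_sign)

    amp = np.zeros(c.n)
    phase = np.zeros(c.n)
    amp[idx] = sign * A
    phase[idx] = 2.0 * np.pi * k * x

    def fn(t):
        return amp * np.sin(omega * t - phase)

    return Stimulus("sinusoidal_drive", c.n, np.inf, fn,
                    {"A": A, "omega": omega, "k": k})


def plm_drive(c: Connectome, amplitude: float) -> Stimulus:
    """Constant current into the PLM touch-receptor pair (tail-touch)."""
    from .connectome import expand_classes
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        members = expand_classes(("PLM",), available=c.neuron_ids)
    if not members:
        raise ValueError("no PLM neurons in this connectome")
    vec = np.zeros(c.n)
    vec[c.index(members)] = amplitude
    return Stimulus.constant(vec, kind="plm_constant", params={"amplitude": amplitude})


def default_conductances(c: Connectome, params: ModelParams) -> ConductancePair:
    """Conductance matrices at the model's per-contact conductance."""
    return conductance_matrices(c, params.g)
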