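"""Synthetic fixtures: surrogate connectomes, decay-trace oracles, planar cycles.

Everything the pipeline consumes can be fabricated here with no download:
random connectomes carrying the statistical structure the simulator needs
(contact totals, E/I labels, soma positions, dorsal/ventral B-class
motorneurons, a miniature motor circuit), voltage traces built from a known
multi-exponential expansion (the exact-recovery oracle for the mode
decomposition), and parametric closed curves for shape-comparison tests.

Each fixture kind draws from its own seeded generator stream, so adding a
new fixture never perturbs the output of existing ones at a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, random_graph_same_edges
from .cycle_analysis import PlanarCycle
from .dynamics import VoltageTrace

__all__ = [
    "surrogate_connectome",
    "decay_trace",
    "DecayTruth",
    "planar_cycle_fixture",
]

# stream tags keeping fixture kinds statistically independent at equal seeds
_STREAMS = {"surrogate_connectome": 101, "decay_trace": 202, "planar_cycle": 303}


def _rng(kind: str, seed) -> np.random.Generator:
    if isinstance(seed, (int, np.integer)):
        return np.random.default_rng([_STREAMS[kind], int(seed)])
    return np.random.default_rng(seed)


def surrogate_connectome(n: int = 40, n_syn: int = 300, n_gap: int = 40,
                         n_bclass: int = 12, ei_fraction: float = 0.8,
                         seed=0) -> Connectome:
    """Random connectome with the anatomical annotations the pipeline needs.

    Topology comes from :func:`random_graph_same_edges`; on top of it,
    every neuron gets a soma position uniform on [0, 1], ``n_bclass``
    neurons are designated B-class motorneurons — named DB*/VB*,
    alternately dorsal/ventral, with strictly increasing soma positions
    along the body — and a handful of cells take motor-circuit names
    (PLM/ALM/AVM sensory, AVA/AVB/PVC/DVA interneurons) so the standard
    circuit-resolution machinery works on surrogates.  Group labels for
    the miniature motor circuit are attached.
    """
    if n_bclass > n:
        raise ValueError("n_bclass cannot exceed n")
    rng = _rng("surrogate_connectome", seed)
    c = random_graph_same_edges(n, n_syn, n_gap, ei_fraction, seed=rng)

    pos = rng.uniform(0.0, 1.0, size=n)
    names = list(c.neuron_ids)
    dv = np.full(n, "none", dtype=object)

    # B-class: alternately dorsal (DB) / ventral (VB), ordered along the body
    b_idx = rng.choice(n, size=n_bclass, replace=False)
    b_idx = b_idx[np.argsort(pos[b_idx])]
    n_db = 0
    n_vb = 0
    b_names = []
    for rank, i in enumerate(b_idx):
        if rank % 2 == 0:
            n_db += 1
            names[i] = f"DB{n_db}"
            dv[i] = "dorsal"
        else:
            n_vb += 1
            names[i] = f"VB{n_vb}"
            dv[i] = "ventral"
        b_names.append(names[i])

    # a miniature motor circuit drawn from the remaining neurons
    rest = [i for i in range(n) if i not in set(b_idx)]
    circuit_names = ["PLML", "PLMR", "ALML", "AVM",
                     "AVBL", "AVBR", "AVAL", "DVA", "PVCL"]
    take = min(len(circuit_names), len(rest))
    chosen = rng.choice(len(rest), size=take, replace=False)
    for slot, ridx in zip(circuit_names, chosen):
        names[rest[ridx]] = slot

    sensory = [nm for nm in ("PLML", "PLMR", "ALML", "AVM") if nm in names]
    inter = [nm for nm in ("AVBL", "AVBR", "AVAL", "DVA", "PVCL") if nm in names]
    groups = {
        "sensory": sensory,
        "interneurons": inter,
        "motorneurons": list(b_names),
        "B_class": list(b_names),
        "motor_circuit": sensory + inter + list(b_names),
    }
    return Connectome(names, c.syn_counts, c.gap_counts, c.ei_class,
                      pos, dv, groups)


@dataclass
class DecayTruth:
    """Generating parameters of a synthetic multi-exponential trace."""

    modes: np.ndarray       # (n, r) orthonormal columns
    taus: np.ndarray        # (r,) seconds
    amplitudes: np.ndarray  # (r,)


def decay_trace(n: int, taus, dt: float = 3e-5, m: int = 3000,
                noise_sd: float = 0.0, seed=0) -> tuple[VoltageTrace, DecayTruth]:
    """Trace built from known decaying modes: V(t_k) = sum_j c_j phi_j e^{-t_k/tau_j}.

    Modes phi_j are random orthonormal directions, amplitudes c_j are
    uniform on [0.5, 2], and optional i.i.d. Gaussian noise (mV) is added.
    Returns the trace together with the generating (phi, tau, c), making
    this the exact-recovery oracle for the mode decomposition.
    """
    taus = np.asarray(taus, dtype=float)
    if (taus <= 0).any():
        raise ValueError("timescales must be positive")
    if len(np.unique(taus)) != taus.size:
        raise ValueError("duplicate timescales")
    r = taus.size
    if m < 2 * r + 2:
        raise ValueError("need m >= 2*len(taus) + 2 snapshots")
    rng = _rng("decay_trace", seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    c = rng.uniform(0.5, 2.0, size=r)
    t = dt * np.arange(m)
    V = (Q * c) @ np.exp(-t[None, :] / taus[:, None])
    if noise_sd > 0:
        V = V + noise_sd * rng.standard_normal(V.shape)
    return VoltageTrace(V, dt), DecayTruth(Q, taus, c)


def planar_cycle_fixture(shape: str = "circle", N: int = 64,
                         noise_sd: float = 0.0, seed=0) -> PlanarCycle:
    """Closed parametric curve sampled uniformly in phase.

    Shapes: ``circle``; ``ellipse`` (2:1 aspect); ``bean`` (an asymmetric
    closed curve with no rotational symmetry, useful for phase-alignment
    tests).  ``noise_sd`` adds relative radial jitter.
    """
    rng = _rng("planar_cycle", seed)
    theta = 2.0 * np.pi * np.arange(N) / N
    if shape == "circle":
        r = np.ones(N)
    elif shape == "ellipse":
        pts = np.vstack([2.0 * np.cos(theta), np.sin(theta)])
        if noise_sd > 0:
            pts *= 1.0 + noise_sd * rng.standard_normal(N)
        return PlanarCycle(pts, period=1.0)
    elif shape == "bean":
        r = 1.0 + 0.25 * np.cos(theta) + 0.1 * np.sin(2.0 * theta)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise_sd > 0:
        r = r * (1.0 + noise_sd * rng.standard_normal(N))
    return PlanarCycle(np.vstack([r * np.cos(theta), r * np.sin(theta)]),
                       period=1.0)
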