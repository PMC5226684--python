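"""Connectome representation, wiring-table I/O, null models, and ablation.

The network is a pair of weighted multigraphs over a fixed, ordered neuron
list: a directed chemical-synapse graph and an undirected gap-junction
graph, both stored as integer contact-count matrices.  The matrix
orientation follows the dynamics convention: ``syn_counts[i, j]`` is the
number of synaptic contacts made by presynaptic neuron ``j`` onto
postsynaptic neuron ``i`` (wiring tables are published as (pre, post) rows,
so the loader transposes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "ConductancePair",
    "load_connectome",
    "write_connectome",
    "conductance_matrices",
    "ablate",
    "degree_preserving_randomization",
    "random_graph_same_edges",
    "motor_circuit",
    "bclass_members",
    "expand_classes",
]

#: dv_label values.  "none" marks neurons without a dorsal/ventral assignment.
DV_LABELS = ("dorsal", "ventral", "none")

#: Motor-circuit composition (sensory / inter / motor classes).
MOTOR_CIRCUIT_CLASSES = {
    "sensory": ("ALM", "AVM", "PLM"),
    "interneurons": ("AVA", "AVB", "AVD", "AVE", "ASH", "AQR", "DVA", "PVC", "PQR"),
    "motorneurons": ("DA", "DB", "DD", "VA", "VB", "VD"),
}


def _class_table() -> dict[str, list[str]]:
    """Neuron-class -> member-cell expansion table (shipped data file)."""
    text = (
        resources.files("wormdmd").joinpath("data/neuron_classes.tsv").read_text()
    )
    table: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, members = line.split("\t")
        table[cls] = members.split(",")
    return table


def expand_classes(classes, available=None) -> list[str]:
    """Expand class names (e.g. ``AVA``, ``DB``) to member cells.

    Names not present in the expansion table are taken verbatim (they may
    already be cell names).  If ``available`` is given, the result is
    restricted to that set and a warning is issued for classes with zero
    resolved members.
    """
    table = _class_table()
    out: list[str] = []
    avail = None if available is None else set(available)
    for cls in classes:
        members = table.get(cls, [cls])
        if avail is not None:
            kept = [m for m in members if m in avail]
            if not kept:
                warnings.warn(f"neuron class {cls!r} has no members in this network")
            out.extend(kept)
        else:
            out.extend(members)
    return out


@dataclass
class Connectome:
    """An ordered neuron list plus synaptic and gap-junction count matrices.

    Attributes
    ----------
    neuron_ids : list of str
        Neuron names; their order fixes all matrix indexing.
    syn_counts : (n, n) int array
        ``syn_counts[i, j]`` = number of chemical synapses from presynaptic
        neuron j onto postsynaptic neuron i.  Zero diagonal.
    gap_counts : (n, n) int array
        Symmetric gap-junction contact counts, zero diagonal.
    ei_class : (n,) str array
        Per-neuron label, "E" (excitatory) or "I" (inhibitory).
    soma_pos : (n,) float array
        Normalized body-axis coordinate in [0, 1]; NaN where unknown.
    dv_label : (n,) str array
        "dorsal" | "ventral" | "none".
    groups : dict
        Named neuron-name subsets (e.g. a motor-circuit partition).
    """

    neuron_ids: list[str]
    syn_counts: np.ndarray
    gap_counts: np.ndarray
    ei_class: np.ndarray
    soma_pos: np.ndarray | None = None
    dv_label: np.ndarray | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.neuron_ids)
        self.syn_counts = np.asarray(self.syn_counts)
        self.gap_counts = np.asarray(self.gap_counts)
        if self.soma_pos is None:
            self.soma_pos = np.full(n, np.nan)
        self.soma_pos = np.asarray(self.soma_pos, dtype=float)
        if self.dv_label is None:
            self.dv_label = np.full(n, "none", dtype=object)
        self.dv_label = np.asarray(self.dv_label, dtype=object)
        self.ei_class = np.asarray(self.ei_class, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = self.n
        for name, mat in (("syn_counts", self.syn_counts), ("gap_counts", self.gap_counts)):
            if mat.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {mat.shape}")
            if not np.issubdtype(mat.dtype, np.integer):
                raise ValueError(f"{name} must be an integer matrix")
            if (mat < 0).any():
                raise ValueError(f"{name} has negative counts")
            if np.diagonal(mat).any():
                raise ValueError(f"{name} has nonzero diagonal (self-contacts)")
        if not np.array_equal(self.gap_counts, self.gap_counts.T):
            raise ValueError("gap_counts must be symmetric")
        if len(set(self.neuron_ids)) != n:
            raise ValueError("duplicate neuron names")
        bad = set(self.ei_class) - {"E", "I"}
        if bad:
            raise ValueError(f"unknown E/I labels: {bad}")
        bad = set(self.dv_label) - set(DV_LABELS)
        if bad:
            raise ValueError(f"unknown dorsal/ventral labels: {bad}")
        known = ~np.isnan(self.soma_pos)
        if ((self.soma_pos[known] < 0) | (self.soma_pos[known] > 1)).any():
            raise ValueError("soma positions must lie in [0, 1]")
        for gname, members in self.groups.items():
            missing = set(members) - set(self.neuron_ids)
            if missing:
                raise ValueError(f"group {gname!r} references unknown neurons {sorted(missing)}")

    # -- convenience ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.neuron_ids)

    def index(self, names) -> np.ndarray:
        """Indices of the given neuron names; hard error on unknown names."""
        lookup = {name: i for i, name in enumerate(self.neuron_ids)}
        missing = [nm for nm in names if nm not in lookup]
        if missing:
            raise KeyError(f"unknown neuron names: {missing}")
        return np.array([lookup[nm] for nm in names], dtype=int)

    @property
    def excitatory(self) -> np.ndarray:
        """Boolean mask, True for excitatory neurons."""
        return self.ei_class == "E"

    @property
    def n_syn(self) -> int:
        """Total number of synaptic contacts."""
        return int(self.syn_counts.sum())

    @property
    def n_gap(self) -> int:
        """Total number of gap-junction contacts (each counted once)."""
        return int(self.gap_counts.sum()) // 2

    def copy(self) -> "Connectome":
        return Connectome(
            list(self.neuron_ids),
            self.syn_counts.copy(),
            self.gap_counts.copy(),
            self.ei_class.copy(),
            self.soma_pos.copy(),
            self.dv_label.copy(),
            {k: list(v) for k, v in self.groups.items()},
        )


@dataclass
class ConductancePair:
    """Gap and synaptic conductance matrices (pS) plus presynaptic E/I mask.

    ``G_gap = g * gap_counts`` (symmetric) and ``G_syn = g * syn_counts``;
    the excitatory mask travels with the matrices because synaptic reversal
    potentials are chosen per presynaptic class.
    """

    G_gap: np.ndarray
    G_syn: np.ndarray
    excitatory: np.ndarray

    @property
    def n(self) -> int:
        return self.G_gap.shape[0]


def conductance_matrices(c: Connectome, g: float = 100.0) -> ConductancePair:
    """Scale contact counts by the per-contact conductance g (pS).

    Every synapse and gap junction carries the same conductance; the model
    default is g = 100 pS.
    """
    if g <= 0:
        raise ValueError(f"per-contact conductance must be positive, got {g}")
    return ConductancePair(
        G_gap=g * c.gap_counts.astype(float),
        G_syn=g * c.syn_counts.astype(float),
        excitatory=c.excitatory.copy(),
    )


# ---------------------------------------------------------------------------
# wiring-table I/O
# ---------------------------------------------------------------------------

def _read_counts(path, n_idx: dict[str, int], *, symmetric: bool,
                 chem_types=("S", "Sp"), gap_types=("G", "EJ")) -> np.ndarray:
    """Parse an edge table into a count matrix.

    Expected columns: pre, post, count and optionally type.  When a type
    column is present, only rows whose type is in the accepted set for this
    table are used (send-side chemical rows for the synapse table, electrical
    rows for the gap table); receive-side duplicates ("R", "Rp") and
    neuromuscular rows ("NMJ") are skipped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(col).strip().lower() for col in df.columns]
    required = {"pre", "post", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: edge table needs columns {sorted(required)}")
    accepted = gap_types if symmetric else chem_types
    n = len(n_idx)
    mat = np.zeros((n, n), dtype=np.int64)
    for row in df.itertuples(index=False):
        rec = row._asdict()
        if "type" in rec:
            typ = str(rec["type"]).strip()
            if typ not in accepted:
                continue
        pre, post = str(rec["pre"]).strip(), str(rec["post"]).strip()
        for nm in (pre, post):
            if nm not in n_idx:
                raise ValueError(f"{path}: unknown neuron {nm!r} in row {rec}")
        cnt = rec["count"]
        if float(cnt) != int(float(cnt)):
            raise ValueError(f"{path}: non-integer count {cnt!r} in row {rec}")
        cnt = int(float(cnt))
        if cnt < 0:
            raise ValueError(f"{path}: negative count in row {rec}")
        if pre == post:
            raise ValueError(f"{path}: self-contact on {pre!r}")
        # dynamics convention: entry (post, pre)
        mat[n_idx[post], n_idx[pre]] += cnt
    if symmetric:
        if not np.array_equal(mat, mat.T):
            both = (mat > 0) & (mat.T > 0) & (mat != mat.T)
            if both.any():
                warnings.warn(
                    "gap table lists inconsistent directional duplicates; "
                    "keeping the larger count per pair"
                )
        mat = np.maximum(mat, mat.T)
    return mat


def load_connectome(neuron_table, synapse_table, gap_table,
                    position_table=None) -> Connectome:
    """Load a connectome from delimited wiring tables.

    Parameters
    ----------
    neuron_table : path
        Columns ``name``, optionally ``ei_class`` ("E"/"I") and ``dv_label``.
    synapse_table, gap_table : path
        Columns ``pre``, ``post``, ``count`` (+ optional ``type``).  The
        synapse table is directed; the gap table is symmetrized by merging
        directional duplicates (larger count wins, with a warning when the
        two directions disagree).
    position_table : path, optional
        Columns ``name``, ``soma_pos`` with normalized positions in [0, 1].

    Neurons listed in the neuron table but absent from the edge tables are
    retained as isolated nodes.
    """
    ndf = pd.read_csv(neuron_table, sep=None, engine="python")
    ndf.columns = [str(col).strip().lower() for col in ndf.columns]
    names = [str(nm).strip() for nm in ndf["name"]]
    n_idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)

    if "ei_class" in ndf.columns:
        ei = np.array([str(x).strip().upper()[:1] for x in ndf["ei_class"]], dtype=object)
    else:
        ei = np.full(n, "E", dtype=object)
    if "dv_label" in ndf.columns:
        dv = np.array(
            [str(x).strip().lower() if str(x).strip().lower() in DV_LABELS else "none"
             for x in ndf["dv_label"]],
            dtype=object,
        )
    else:
        dv = None

    syn = _read_counts(synapse_table, n_idx, symmetric=False)
    gap = _read_counts(gap_table, n_idx, symmetric=True)

    pos = np.full(n, np.nan)
    if position_table is not None:
        pdf = pd.read_csv(position_table, sep=None, engine="python")
        pdf.columns = [str(col).strip().lower() for col in pdf.columns]
        for row in pdf.itertuples(index=False):
            nm = str(row.name).strip() if hasattr(row, "name") else None
            rec = row._asdict()
            nm = str(rec["name"]).strip()
            if nm not in n_idx:
                raise ValueError(f"{position_table}: unknown neuron {nm!r}")
            pos[n_idx[nm]] = float(rec["soma_pos"])

    return Connectome(names, syn, gap, ei, pos, dv)


def write_connectome(c: Connectome, outdir) -> dict[str, Path]:
    """Write the four wiring tables; inverse of :func:`load_connectome`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "neurons": outdir / "neurons.csv",
        "synapses": outdir / "synapses.csv",
        "gaps": outdir / "gaps.csv",
        "positions": outdir / "positions.csv",
    }
    pd.DataFrame({
        "name": c.neuron_ids, "ei_class": c.ei_class, "dv_label": c.dv_label,
    }).to_csv(paths["neurons"], index=False)
    post, pre = np.nonzero(c.syn_counts)
    pd.DataFrame({
        "pre": [c.neuron_ids[j] for j in pre],
        "post": [c.neuron_ids[i] for i in post],
        "count": c.syn_counts[post, pre],
    }).to_csv(paths["synapses"], index=False)
    iu, ju = np.nonzero(np.triu(c.gap_counts))
    pd.DataFrame({
        "pre": [c.neuron_ids[i] for i in iu],
        "post": [c.neuron_ids[j] for j in ju],
        "count": c.gap_counts[iu, ju],
    }).to_csv(paths["gaps"], index=False)
    known = ~np.isnan(c.soma_pos)
    pd.DataFrame({
        "name": [nm for nm, k in zip(c.neuron_ids, known) if k],
        "soma_pos": c.soma_pos[known],
    }).to_csv(paths["positions"], index=False)
    return paths


# ---------------------------------------------------------------------------
# ablation and null models
# ---------------------------------------------------------------------------

def ablate(c: Connectome, names) -> Connectome:
    """Remove all connections of the named neurons (simulated ablation).

    Rows and columns of both count matrices are zeroed for every ablated
    neuron; the neuron list, classes and positions are unchanged, so ablated
    cells remain as disconnected nodes.
    """
    idx = c.index(list(names))
    out = c.copy()
    out.syn_counts[idx, :] = 0
    out.syn_counts[:, idx] = 0
    out.gap_counts[idx, :] = 0
    out.gap_counts[:, idx] = 0
    return out


def _contacts_directed(mat: np.ndarray) -> np.ndarray:
    """Expand a directed count matrix into an (n_contacts, 2) (pre, post) list."""
    post, pre = np.nonzero(mat)
    counts = mat[post, pre]
    return np.column_stack([np.repeat(pre, counts), np.repeat(post, counts)])


def _contacts_undirected(mat: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(mat))
    counts = mat[iu, ju]
    return np.column_stack([np.repeat(iu, counts), np.repeat(ju, counts)])


def degree_preserving_randomization(c: Connectome, seed,
                                    swap_factor: int = 10) -> Connectome:
    """Rewire both multigraphs preserving every neuron's multidegree exactly.

    Repeated double-edge swaps on the contact lists: for the directed
    synapse graph a swap (a->b, c->d) -> (a->d, c->b) preserves each node's
    in- and out-multidegree; for the undirected gap graph the analogous
    endpoint exchange preserves gap multidegree and symmetry.  Swaps that
    would create self-loops are rejected.  ``swap_factor`` sets the number
    of attempted swaps per contact (default 10).
    """
    rng = np.random.default_rng(seed)
    out = c.copy()

    syn = _contacts_directed(c.syn_counts)
    if len(syn) >= 2:
        n_attempts = swap_factor * len(syn)
        pairs = rng.integers(0, len(syn), size=(n_attempts, 2))
        for e1, e2 in pairs:
            if e1 == e2:
                continue
            a, b = syn[e1]
            cc, d = syn[e2]
            if a == d or cc == b:
                continue
            syn[e1, 1], syn[e2, 1] = d, b
        mat = np.zeros_like(c.syn_counts)
        np.add.at(mat, (syn[:, 1], syn[:, 0]), 1)  # (post, pre) indexing
        out.syn_counts = mat

    gap = _contacts_undirected(c.gap_counts)
    if len(gap) >= 2:
        n_attempts = swap_factor * len(gap)
        pairs = rng.integers(0, len(gap), size=(n_attempts, 2))
        flips = rng.integers(0, 2, size=n_attempts)
        for (e1, e2), flip in zip(pairs, flips):
            if e1 == e2:
                continue
            a, b = gap[e1]
            cc, d = gap[e2]
            if flip:  # exchange the other endpoint
                cc, d = d, cc
            if a == d or b == cc:
                continue
            gap[e1] = (a, d)
            gap[e2] = (cc, b)
        mat = np.zeros_like(c.gap_counts)
        np.add.at(mat, (gap[:, 0], gap[:, 1]), 1)
        mat = mat + mat.T
        out.gap_counts = mat

    out.validate()
    return out


def random_graph_same_edges(n: int, n_syn: int, n_gap: int,
                            ei_fraction: float = 0.8, seed=None) -> Connectome:
    """Uniformly random multigraphs with the given total contact counts.

    Synaptic contacts are placed uniformly over ordered off-diagonal pairs
    (multi-edges allowed), gap contacts over unordered pairs; E/I labels are
    drawn independently with probability ``ei_fraction`` of excitatory.
    """
    if n < 2:
        raise ValueError("need at least 2 neurons")
    if n_syn < 0 or n_gap < 0:
        raise ValueError("edge totals must be nonnegative")
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n)]

    syn = np.zeros((n, n), dtype=np.int64)
    if n_syn:
        pre = rng.integers(0, n, size=n_syn)
        off = rng.integers(1, n, size=n_syn)
        post = (pre + off) % n  # uniform over j != i
        np.add.at(syn, (post, pre), 1)

    gap = np.zeros((n, n), dtype=np.int64)
    if n_gap:
        a = rng.integers(0, n, size=n_gap)
        off = rng.integers(1, n, size=n_gap)
        b = (a + off) % n
        np.add.at(gap, (a, b), 1)
        gap = gap + gap.T

    ei = np.where(rng.random(n) < ei_fraction, "E", "I").astype(object)
    return Connectome(names, syn, gap, ei)


# ---------------------------------------------------------------------------
# motor circuit
# ---------------------------------------------------------------------------

def motor_circuit(c: Connectome) -> dict[str, list[str]]:
    """Resolve the locomotion motor circuit on this connectome.

    Returns the named subsets ``sensory`` (ALM, AVM, PLM), ``interneurons``
    (AVA, AVB, AVD, AVE, ASH, AQR, DVA, PVC, PQR), ``motorneurons`` (DA, DB,
    DD, VA, VB, VD) and ``B_class`` (DB + VB members).  Classes with no
    member in the network produce a warning, not an error, so surrogate
    connectomes with partial naming still resolve.
    """
    avail = c.neuron_ids
    subsets = {
        name: expand_classes(classes, available=avail)
        for name, classes in MOTOR_CIRCUIT_CLASSES.items()
    }
    subsets["B_class"] = expand_classes(("DB", "VB"), available=avail)
    return subsets


def bclass_members(c: Connectome) -> list[str]:
    """B-class motorneurons: an explicit ``B_class`` group if present, else
    the DB/VB members resolved by name."""
    if "B_class" in c.groups:
        return list(c.groups["B_class"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return motor_circuit(c)["B_class"]
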