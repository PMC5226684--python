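"""Orchestration of the three experiments: impulse-ensemble mode
decomposition, driven-cycle wavelength scan, and altered-connectome
comparison.

All randomness flows from one master seed through a spawned
``numpy.random.SeedSequence`` tree, so a run is fully determined by its
configuration; with an output directory set, per-trial archives and a JSON
manifest are written, and completed trials are skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .connectome import (Connectome, ablate, conductance_matrices,
                         degree_preserving_randomization, load_connectome,
                         random_graph_same_edges)
from .cycle_analysis import (NoCycleError, PlanarCycle, extract_period,
                             phase_align, project_plane, resample_cycle)
from .dmd import DMDResult, exact_dmd, fit_amplitudes, snapshot_matrices
from .dynamics import (ModelParams, NetworkState, Stimulus, VoltageTrace,
                       find_fixed_point, integrate, proprioceptive_drive,
                       random_impulse)
from .mode_analysis import (ModeEnsemble, PLMModes, aggregate_trials,
                            ks_compare, plm_modes)
from .synthetic import surrogate_connectome

__all__ = [
    "ExperimentConfig",
    "ImpulseRun",
    "DrivenCycleRun",
    "run_impulse_ensemble",
    "run_driven_cycle",
    "run_network_comparison",
]


@dataclass
class ExperimentConfig:
    """Everything a run needs; YAML-serializable.

    ``connectome`` either points at wiring tables
    (``{"tables": {"neurons": ..., "synapses": ..., "gaps": ...,
    "positions": ...}}``) or requests a surrogate
    (``{"surrogate": {"n": 40, ...}}``).  Integration uses step ``h`` with
    voltages recorded every ``dt_record``; impulse trials decay for ``T``
    seconds (about five times the slowest network timescale), driven runs
    last ``T_drive``.  ``seed`` is the root of the seed tree.
    """

    connectome: dict = field(default_factory=lambda: {"surrogate": {}})
    params: dict = field(default_factory=dict)   # ModelParams overrides
    n_trials: int = 10
    seed: int = 0
    # impulse-decay integration
    T: float = 0.5
    h: float = 1e-5
    dt_record: float = 3e-5
    impulse_amplitude: float = 10.0
    impulse_duration: float = 1e-5
    energy_threshold: float = 0.99
    energy: str = "sigma"
    # sinusoidal proprioceptive drive
    drive_A: float = 30.0
    drive_omega: float = 25.0
    reference_k: float = 0.886
    k_grid: list = field(default_factory=lambda: [0.443, 0.886, 1.772])
    T_drive: float = 2.0
    dt_record_drive: float = 1e-3
    transient_fraction: float = 0.5
    resample_N: int = 200
    # altered-connectome comparison
    n_altered_networks: int = 2
    n_altered_trials: int = 3
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def model_params(self) -> ModelParams:
        return ModelParams(**self.params)

    def build_connectome(self) -> Connectome:
        if "tables" in self.connectome:
            t = self.connectome["tables"]
            return load_connectome(t["neurons"], t["synapses"], t["gaps"],
                                   t.get("positions"))
        return surrogate_connectome(**self.connectome.get("surrogate", {}))


@dataclass
class ImpulseRun:
    """Results of an impulse-response ensemble on one network."""

    connectome: Connectome
    params: ModelParams
    fixed_point: NetworkState
    results: list[DMDResult]
    flags: list[str]            # per-trial anomaly notes ("" = clean)
    manifest: dict

    def aggregate(self, modes: PLMModes) -> ModeEnsemble:
        return aggregate_trials(self.results, modes)


def _prepare(cfg: ExperimentConfig, connectome: Connectome | None):
    c = connectome if connectome is not None else cfg.build_connectome()
    cond = conductance_matrices(c, cfg.model_params().g)
    params = cfg.model_params().with_thresholds(cond)
    fp = find_fixed_point(cond, params)
    return c, cond, params, fp


def _impulse_trial(cond, params, fp, cfg: ExperimentConfig, seed):
    """One trial: impulse, decay, deviation trace, mode decomposition."""
    stim = random_impulse(cond.n, seed, cfg.impulse_amplitude,
                          cfg.impulse_duration)
    trace = integrate(fp, cond, params, stim, T=cfg.T, h=cfg.h,
                      dt_record=cfg.dt_record, record_start=stim.duration)
    dev = trace.V - fp.v[:, None]
    flag = ""
    norms = np.linalg.norm(dev, axis=0)
    tail = max(2, len(norms) // 10)
    if norms[-1] > norms[-tail]:
        flag = "deviation norm growing over final 10% of trace"
    devtrace = VoltageTrace(dev, trace.dt_record, trace.t0)
    X, Xp = snapshot_matrices(devtrace)
    res = exact_dmd(X, Xp, cfg.energy_threshold, cfg.dt_record, cfg.energy)
    fit_amplitudes(res, dev[:, 0])
    return res, flag


def run_impulse_ensemble(cfg: ExperimentConfig,
                         connectome: Connectome | None = None) -> ImpulseRun:
    """Perturb the network from equilibrium ``cfg.n_trials`` times and
    decompose each decay.

    Each trial draws an independent random impulse, integrates the free
    decay back to the fixed point, subtracts the fixed point (the analysis
    operates on deviations, removing the constant background that would
    otherwise appear as a unit-eigenvalue mode), and applies the mode
    decomposition at the configured energy threshold.  Trials failing to
    decay are flagged but kept.
    """
    c, cond, params, fp = _prepare(cfg, connectome)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trials)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    results, flags = [], []
    for t, child in enumerate(seeds):
        archive = outdir / f"trial_{t:04d}.h5" if outdir else None
        if archive is not None and archive.exists():
            results.append(wio.load_dmd(archive))
            flags.append("")
            continue
        res, flag = _impulse_trial(cond, params, fp, cfg, child)
        results.append(res)
        flags.append(flag)
        if archive is not None:
            archive.parent.mkdir(parents=True, exist_ok=True)
            wio.save_dmd(archive, res)
    manifest = {
        "config": cfg.to_dict(),
        "seed_states": [s.entropy for s in seeds],
        "n_neurons": c.n,
        "mode_counts": [r.eigenvalues.size for r in results],
        "flags": flags,
    }
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        wio.write_manifest(outdir / "manifest.json", manifest)
    if any(flags):
        warnings.warn(f"{sum(map(bool, flags))} flagged trial(s); see manifest")
    return ImpulseRun(c, params, fp, results, flags, manifest)


@dataclass
class DrivenCycleRun:
    """Reference driven cycle, its plane/displacement modes, and the scan table."""

    connectome: Connectome
    params: ModelParams
    fixed_point: NetworkState
    reference: PlanarCycle
    modes: PLMModes
    table: pd.DataFrame


def _driven_trace(c, cond, params, fp, cfg: ExperimentConfig, k: float,
                  omega: float | None = None) -> VoltageTrace:
    stim = proprioceptive_drive(c, A=cfg.drive_A,
                                omega=cfg.drive_omega if omega is None else omega,
                                k=k)
    return integrate(fp, cond, params, stim, T=cfg.T_drive, h=cfg.h,
                     dt_record=cfg.dt_record_drive)


def run_driven_cycle(cfg: ExperimentConfig, k_grid=None,
                     connectome: Connectome | None = None) -> DrivenCycleRun:
    """Scan the spatial wavenumber of the proprioceptive traveling-wave drive.

    The reference cycle is simulated at ``cfg.reference_k`` (0.886 cycles
    per body length, wavelength 1.13 body lengths); its plane modes and
    displacement mode are extracted, and each k in the grid is scored by
    the phase-aligned Procrustes distance of its plane-projected cycle to
    the reference.  Wavenumbers producing no periodic response get a NaN
    distance with a note.
    """
    c, cond, params, fp = _prepare(cfg, connectome)
    ks = list(k_grid if k_grid is not None else cfg.k_grid)
    if not any(np.isclose(k, cfg.reference_k) for k in ks):
        ks.append(cfg.reference_k)
    ks = sorted(ks)

    ref_trace = _driven_trace(c, cond, params, fp, cfg, cfg.reference_k)
    modes = plm_modes(ref_trace, fp.v)
    ref_traj = project_plane(ref_trace, modes)
    ref_cycle = resample_cycle(
        extract_period(ref_traj, cfg.dt_record_drive, cfg.transient_fraction),
        cfg.resample_N)

    rows = []
    for k in ks:
        try:
            trace = (_driven_trace(c, cond, params, fp, cfg, k)
                     if not np.isclose(k, cfg.reference_k) else ref_trace)
            traj = project_plane(trace, modes)
            cyc = resample_cycle(
                extract_period(traj, cfg.dt_record_drive, cfg.transient_fraction),
                cfg.resample_N)
            _, dist = phase_align(cyc, ref_cycle)
            rows.append({"k": k, "period": cyc.period, "distance": dist, "note": ""})
        except NoCycleError as err:
            rows.append({"k": k, "period": np.nan, "distance": np.nan,
                         "note": f"no-cycle: {err}"})
    table = pd.DataFrame(rows).sort_values("k").reset_index(drop=True)
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "driven_cycle_scan.csv", index=False)
    return DrivenCycleRun(c, params, fp, ref_cycle, modes, table)


def _family_networks(kind: str, standard: Connectome, cfg: ExperimentConfig,
                     seeds) -> list[Connectome]:
    if kind == "degree_preserving":
        return [degree_preserving_randomization(standard, s) for s in seeds]
    if kind == "random_graph":
        ei_fraction = float(np.mean(standard.excitatory))
        return [random_graph_same_edges(standard.n, standard.n_syn,
                                        standard.n_gap, ei_fraction, s)
                for s in seeds]
    raise ValueError(f"unknown network family {kind!r}")


def run_network_comparison(cfg: ExperimentConfig,
                           connectome: Connectome | None = None,
                           families=("degree_preserving", "random_graph")) -> pd.DataFrame:
    """Compare mode statistics of the standard network against altered families.

    For each family (exact-degree-sequence rewiring; fully random with the
    same contact totals), ``cfg.n_altered_networks`` networks are generated
    and probed with ``cfg.n_altered_trials`` impulse trials each.  Per mode
    index and statistic (timescale, displacement projection, plane
    projection), each altered network's sample is tested against the
    standard ensemble with the two-sample Kolmogorov-Smirnov test and the
    per-family *maximum* p-value is reported.  When a family's mode count
    differs from the standard's, the comparison is restricted to the
    common fastest indices and noted.
    """
    c = connectome if connectome is not None else cfg.build_connectome()
    root = np.random.SeedSequence(cfg.seed)
    ss_std, ss_nets, ss_trials = root.spawn(3)

    std_run = run_impulse_ensemble(
        dataclasses.replace(cfg, outdir=None,
                            seed=int(ss_std.generate_state(1)[0])), c)

    # reference modes from the standard network's driven cycle
    cond = conductance_matrices(c, std_run.params.g)
    ref_trace = _driven_trace(c, cond, std_run.params, std_run.fixed_point,
                              cfg, cfg.reference_k)
    modes = plm_modes(ref_trace, std_run.fixed_point.v)
    std_ens = std_run.aggregate(modes)

    net_seeds = ss_nets.spawn(cfg.n_altered_networks * len(families))
    rows = []
    for f_i, family in enumerate(families):
        seeds = net_seeds[f_i * cfg.n_altered_networks:(f_i + 1) * cfg.n_altered_networks]
        nets = _family_networks(family, c, cfg, seeds)
        ensembles = []
        for net, child in zip(nets, ss_trials.spawn(len(nets))):
            trial_cfg = dataclasses.replace(
                cfg, outdir=None, n_trials=cfg.n_altered_trials,
                seed=int(child.generate_state(1)[0]))
            run = run_impulse_ensemble(trial_cfg, net)
            ensembles.append(run.aggregate(modes))
        r_common = min([std_ens.r] + [e.r for e in ensembles])
        note = ("" if r_common == std_ens.r == max(e.r for e in ensembles)
                else f"mode counts differ; comparing fastest {r_common}")
        for j in range(r_common):
            for stat, std_data in (("tau", std_ens.taus), ("disp", std_ens.disp),
                                   ("plane", std_ens.plane)):
                pmax = max(
                    ks_compare(std_data[:, j],
                               {"tau": e.taus, "disp": e.disp,
                                "plane": e.plane}[stat][:, j])
                    for e in ensembles)
                rows.append({"family": family, "mode": j + 1, "stat": stat,
                             "max_p": pmax, "note": note})
    df = pd.DataFrame(rows)
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "network_comparison.csv", index=False)
    return df
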