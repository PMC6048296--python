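"""Balanced random network (BRN) simulator.

Leaky integrate-and-fire neurons with exponential-current synapses,
integrated with the exact propagator of the linear subthreshold system on
a fixed grid (default 0.05 ms, spike times limited to the grid).  Ships
the classic weak-synapse configuration, the strong-synapse variant, and
the variants adjusted for realistic membrane properties, synaptic
strengths, and volume-averaged connection probabilities, together with
the stimulation/ablation protocols used to probe excitability and
excitatory-inhibitory coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structural import MembraneParams, SynapseKernel, psc_for_psp
from .spiketrain import EXC, INH, SpikeRaster
from .subthreshold import AnalogTrace

__all__ = [
    "BrnConfig",
    "NetworkRealization",
    "RecordingSpec",
    "SimulationResult",
    "SimulationDivergedError",
    "preset",
    "PRESETS",
    "build_network",
    "external_rate_threshold",
    "simulate",
    "excitability_test",
    "self_sustained_test",
    "ramp_drive",
    "parameter_scan",
]


class SimulationDivergedError(RuntimeError):
    def __init__(self, t_ms: float):
        super().__init__(f"runaway excitation: numeric overflow at t = {t_ms:.1f} ms")
        self.t_ms = t_ms


@dataclass
class BrnConfig:
    """Full parameter set of one network variant.

    ``connectivity`` is either ``{"p": x}`` (uniform: fixed in-degrees
    Ce = Ne*p and Ci = Ni*p per neuron) or per-type probabilities
    ``{"e<-e": ..., "i<-e": ..., "e<-i": ..., "i<-i": ...}``.  Scale
    factors k multiply the three non-e<-e weights.
    """

    Ne: int = 8000
    Ni: int = 2000
    connectivity: dict = field(default_factory=lambda: {"p": 0.1})
    J: float = 6.3  # pA, excitatory PSC amplitude
    g: float = 5.0  # inhibitory/excitatory weight ratio
    k_ei: float = 1.0  # scales w(e<-i)
    k_ie: float = 1.0  # scales w(i<-e)
    k_ii: float = 1.0  # scales w(i<-i)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    syn: SynapseKernel = field(default_factory=SynapseKernel)
    theta: float = 1.5
    dt: float = 0.05
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.Ne <= 0 or self.Ni <= 0:
            raise ValueError("population sizes must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        ratio = self.syn.delay / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or self.syn.delay < self.dt:
            raise ValueError("delay must be a positive multiple of dt")

    @property
    def N(self) -> int:
        return self.Ne + self.Ni


def _table2_membrane() -> MembraneParams:
    return MembraneParams(Cm=100.0, tau_m=20.0, Vrest=0.0, Vth=20.0, Vr=10.0, tau_ref=2.0)


def table2() -> BrnConfig:
    """Classic BRN with weak exponential synapses (PSP_e<-e = 0.2 mV)."""
    return BrnConfig(
        Ne=8000, Ni=2000, connectivity={"p": 0.1}, J=6.3, g=5.0,
        membrane=_table2_membrane(),
        syn=SynapseKernel(J=6.3, tau_syn=5.0, delay=1.5),
        theta=1.5, name="table2",
    )


def table4() -> BrnConfig:
    """BRN with strong synapses (PSP_e<-e = 0.8 mV, short delay/refractoriness)."""
    mem = MembraneParams(Cm=100.0, tau_m=20.0, Vrest=0.0, Vth=20.0, Vr=10.0, tau_ref=0.5)
    return BrnConfig(
        Ne=8000, Ni=2000, connectivity={"p": 0.1}, J=25.4, g=5.0,
        membrane=mem, syn=SynapseKernel(J=25.4, tau_syn=5.0, delay=0.55),
        theta=1.5, name="table4",
    )


def _table3(J: float, base: BrnConfig, name: str) -> BrnConfig:
    mem = replace(base.membrane, tau_m=6.7)
    return replace(
        base,
        Ne=4800, Ni=1200,
        connectivity={"e<-e": 0.07, "i<-e": 0.24, "e<-i": 0.24, "i<-i": 0.24},
        J=J, membrane=mem, syn=replace(base.syn, J=J), name=name,
    )


def table3_weak() -> BrnConfig:
    """Realistic-parameter variant with weak synapses (PSP_e<-e = 0.1 mV)."""
    return _table3(4.7, table2(), "table3-weak")


def table3_strong() -> BrnConfig:
    """Realistic-parameter variant with strong synapses (PSP_e<-e = 0.6 mV)."""
    return _table3(28.4, table4(), "table3-strong")


PRESETS = {
    "table2": table2,
    "table3-weak": table3_weak,
    "table3-strong": table3_strong,
    "table4": table4,
}


def preset(name: str) -> BrnConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass
class NetworkRealization:
    """Frozen wiring: out-adjacency in CSR form with per-edge weights.

    Neurons 0..Ne-1 are excitatory, Ne..N-1 inhibitory.  No autapses, no
    multapses; in uniform mode every neuron has exactly (Ce, Ci) inputs.
    """

    indptr: np.ndarray  # (N+1,) int64
    targets: np.ndarray  # (n_edges,) int32, sorted by source
    weights: np.ndarray  # (n_edges,) float64, pA
    Ne: int
    Ni: int
    seed: int

    @property
    def N(self) -> int:
        return self.Ne + self.Ni

    def out_edges(self, source: int) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(self.indptr[source], self.indptr[source + 1])
        return self.targets[sl], self.weights[sl]

    def in_degrees(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron (excitatory, inhibitory) in-degree."""
        exc_mask = np.zeros(len(self.targets), dtype=bool)
        for s in range(self.Ne):
            exc_mask[self.indptr[s] : self.indptr[s + 1]] = True
        de = np.bincount(self.targets[exc_mask], minlength=self.N)
        di = np.bincount(self.targets[~exc_mask], minlength=self.N)
        return de, di


def _edge_weights(src: np.ndarray, tgt: np.ndarray, cfg: BrnConfig) -> np.ndarray:
    src_exc = src < cfg.Ne
    tgt_exc = tgt < cfg.Ne
    w = np.empty(src.size, dtype=float)
    w[src_exc & tgt_exc] = cfg.J
    w[src_exc & ~tgt_exc] = cfg.k_ie * cfg.J
    w[~src_exc & tgt_exc] = -cfg.g * cfg.J * cfg.k_ei
    w[~src_exc & ~tgt_exc] = -cfg.g * cfg.J * cfg.k_ii
    return w


def build_network(cfg: BrnConfig, seed: int = 0) -> NetworkRealization:
    """Draw a random wiring: fixed per-type in-degrees, no autapses/multapses.

    Uniform mode: every neuron receives exactly Ce = round(Ne*p) excitatory
    and Ci = round(Ni*p) inhibitory inputs drawn without replacement,
    excluding itself.  Per-type mode: in-degree round(N_source * p_type).
    """
    rng = np.random.default_rng(seed)
    N, Ne, Ni = cfg.N, cfg.Ne, cfg.Ni
    if "p" in cfg.connectivity:
        p = cfg.connectivity["p"]
        deg = {("e", "e"): round(Ne * p), ("e", "i"): round(Ne * p),
               ("i", "e"): round(Ni * p), ("i", "i"): round(Ni * p)}
    else:
        c = cfg.connectivity
        deg = {("e", "e"): round(Ne * c["e<-e"]), ("e", "i"): round(Ne * c["i<-e"]),
               ("i", "e"): round(Ni * c["e<-i"]), ("i", "i"): round(Ni * c["i<-i"])}
    for (srcpop, _), d in deg.items():
        avail = Ne if srcpop == "e" else Ni
        if d >= avail:
            raise ValueError("requested in-degree exceeds available sources")

    src_parts, tgt_parts = [], []
    for tgt in range(N):
        tgtpop = "e" if tgt < Ne else "i"
        # excitatory sources, excluding self if the target is excitatory
        d_e = deg[("e", tgtpop)]
        if tgtpop == "e":
            s = rng.choice(Ne - 1, size=d_e, replace=False)
            s[s >= tgt] += 1
        else:
            s = rng.choice(Ne, size=d_e, replace=False)
        src_parts.append(s)
        # inhibitory sources
        d_i = deg[("i", tgtpop)]
        if tgtpop == "i":
            s = rng.choice(Ni - 1, size=d_i, replace=False)
            s[s >= tgt - Ne] += 1
        else:
            s = rng.choice(Ni, size=d_i, replace=False)
        src_parts.append(s + Ne)
        tgt_parts.append(np.full(d_e + d_i, tgt, dtype=np.int32))

    src = np.concatenate(src_parts).astype(np.int64)
    tgt = np.concatenate(tgt_parts).astype(np.int32)
    order = np.argsort(src, kind="stable")
    src, tgt = src[order], tgt[order]
    indptr = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=N), out=indptr[1:])
    return NetworkRealization(
        indptr=indptr, targets=tgt, weights=_edge_weights(src, tgt, cfg),
        Ne=Ne, Ni=Ni, seed=seed,
    )


def rescale_weights(net: NetworkRealization, cfg: BrnConfig) -> NetworkRealization:
    """Recompute per-edge weights (e.g. after changing k scale factors)
    on an existing topology."""
    src = np.repeat(np.arange(net.N), np.diff(net.indptr))
    return replace(net, weights=_edge_weights(src, net.targets, cfg))


def external_rate_threshold(cfg: BrnConfig) -> float:
    """Total Poisson event rate per neuron (events/ms) at which the
    stationary mean membrane potential of an isolated passive neuron
    equals the spike threshold.

    Each drive event deposits a PSC of amplitude J (charge J*tau_syn);
    the stationary mean potential is rate * J * tau_syn * tau_m / Cm, so
    nu = (Vth - Vrest) * Cm / (J * tau_syn * tau_m).  The drive runs at
    theta times this rate.
    """
    if cfg.J <= 0:
        raise ValueError("J must be positive")
    m = cfg.membrane
    return (m.Vth - m.Vrest) * m.Cm / (cfg.J * cfg.syn.tau_syn * m.tau_m)


@dataclass
class RecordingSpec:
    """Which neurons to record intracellularly.

    Membrane potentials are decimated to 0.1 ms; synaptic currents are
    kept at the simulation resolution (0.05 ms), separately for the
    excitatory and inhibitory components.
    """

    neuron_ids: list[int] | None = None
    n_vm: int = 50
    vm_dt: float = 0.1

    def resolve(self, cfg: BrnConfig) -> list[int]:
        if self.neuron_ids is not None:
            return list(self.neuron_ids)
        return list(range(min(self.n_vm, cfg.Ne)))


@dataclass
class SimulationResult:
    raster: SpikeRaster
    vm_traces: dict[int, AnalogTrace]
    exc_current_traces: dict[int, AnalogTrace]
    inh_current_traces: dict[int, AnalogTrace]
    config: BrnConfig
    seed: int
    theta_schedule: list[tuple[float, float]]

    @property
    def duration(self) -> float:
        return self.raster.duration


def _run(
    net: NetworkRealization,
    cfg: BrnConfig,
    schedule: list[tuple[float, float]],
    seed: int,
    record: RecordingSpec | None,
    injections: list[tuple[float, int, float]] | None = None,
    init: str = "uniform",
) -> SimulationResult:
    rng = np.random.default_rng(seed)
    m, dt = cfg.membrane, cfg.dt
    N, Ne = cfg.N, cfg.Ne
    n_steps = int(round(sum(d for d, _ in schedule) / dt))
    delay_steps = int(round(cfg.syn.delay / dt))
    n_slots = delay_steps + 1
    ref_steps = int(round(m.tau_ref / dt))

    # exact propagator of the linear (V, Ie, Ii) system over one step
    em = np.exp(-dt / m.tau_m)
    es = np.exp(-dt / cfg.syn.tau_syn)
    if np.isclose(m.tau_m, cfg.syn.tau_syn, rtol=1e-12):
        pI = dt * np.exp(-dt / m.tau_m) / m.Cm
    else:
        pI = (es - em) * m.tau_m * cfg.syn.tau_syn / (m.Cm * (cfg.syn.tau_syn - m.tau_m))

    # per-step drive rate (events per neuron per step)
    nu = external_rate_threshold(cfg)
    lam_steps = np.empty(n_steps)
    pos = 0
    for seg_dur, theta in schedule:
        n = int(round(seg_dur / dt))
        lam_steps[pos : pos + n] = theta * nu * dt
        pos += n

    if init == "uniform":
        V = m.Vrest + (m.Vth - m.Vrest) * rng.random(N)
    else:
        V = np.full(N, m.Vrest)
    Ie = np.zeros(N)
    Ii = np.zeros(N)
    refr = np.zeros(N, dtype=np.int64)
    buf_e = np.zeros((n_slots, N))
    buf_i = np.zeros((n_slots, N))

    # pending external injections, grouped by delivery step
    pending: dict[int, list[tuple[int, float]]] = {}
    for t_ms, nid, w in injections or []:
        pending.setdefault(int(round(t_ms / dt)), []).append((nid, w))

    rec_ids = record.resolve(cfg) if record else []
    rec_idx = np.array(rec_ids, dtype=np.int64)
    vm_stride = max(int(round((record.vm_dt if record else 0.1) / dt)), 1)
    n_vm = n_steps // vm_stride
    rec_vm = np.empty((n_vm, rec_idx.size), dtype=np.float32) if rec_ids else None
    rec_ie = np.empty((n_steps, rec_idx.size), dtype=np.float32) if rec_ids else None
    rec_ii = np.empty((n_steps, rec_idx.size), dtype=np.float32) if rec_ids else None

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []
    exc_drive = cfg.J  # the external drive delivers PSCs of amplitude J

    for j in range(n_steps):
        slot = j % n_slots
        Ie += buf_e[slot]
        Ii += buf_i[slot]
        buf_e[slot] = 0.0
        buf_i[slot] = 0.0
        if lam_steps[j] > 0:
            Ie += exc_drive * rng.poisson(lam_steps[j], N)
        for nid, w in pending.get(j, ()):
            if w >= 0:
                Ie[nid] += w
            else:
                Ii[nid] += w
        if rec_ids:
            rec_ie[j] = Ie[rec_idx]
            rec_ii[j] = Ii[rec_idx]

        V = m.Vrest + em * (V - m.Vrest) + pI * (Ie + Ii)
        Ie *= es
        Ii *= es

        in_ref = refr > 0
        if in_ref.any():
            V[in_ref] = m.Vr
            refr[in_ref] -= 1

        spiked = V >= m.Vth
        if spiked.any():
            ids = np.flatnonzero(spiked)
            V[ids] = m.Vr
            refr[ids] = ref_steps
            spike_steps.append(np.full(ids.size, j + 1, dtype=np.int64))
            spike_ids.append(ids)
            dslot = (j + 1 + delay_steps) % n_slots
            for s in ids:
                t0, t1 = net.indptr[s], net.indptr[s + 1]
                tg = net.targets[t0:t1]
                w = net.weights[t0:t1]
                if s < Ne:
                    np.add.at(buf_e[dslot], tg, w)
                else:
                    np.add.at(buf_i[dslot], tg, w)
            if ids.size > 0.9 * N or not np.isfinite(V).all():
                raise SimulationDivergedError((j + 1) * dt)

        if rec_ids and (j + 1) % vm_stride == 0:
            rec_vm[(j + 1) // vm_stride - 1] = V[rec_idx]

    duration = n_steps * dt
    all_ids = np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=int)
    all_t = dt * np.concatenate(spike_steps) if spike_steps else np.empty(0)
    labels = {n: (EXC if n < Ne else INH) for n in range(N)}
    raster = SpikeRaster.from_arrays(all_ids, all_t, labels, duration, origin="simulation")

    vm_traces, ie_traces, ii_traces = {}, {}, {}
    for k, nid in enumerate(rec_ids):
        vm_traces[nid] = AnalogTrace(
            rec_vm[:, k].astype(float), dt=vm_stride * dt, kind="vm",
            channel_id=nid, t0=vm_stride * dt,
        )
        ie_traces[nid] = AnalogTrace(
            rec_ie[:, k].astype(float), dt=dt, kind="exc_current", channel_id=nid, t0=0.0
        )
        ii_traces[nid] = AnalogTrace(
            rec_ii[:, k].astype(float), dt=dt, kind="inh_current", channel_id=nid, t0=0.0
        )
    return SimulationResult(
        raster=raster, vm_traces=vm_traces,
        exc_current_traces=ie_traces, inh_current_traces=ii_traces,
        config=cfg, seed=seed, theta_schedule=list(schedule),
    )


def simulate(
    net: NetworkRealization,
    cfg: BrnConfig,
    duration: float,
    seed: int = 0,
    record: RecordingSpec | None = RecordingSpec(),
    injections: list[tuple[float, int, float]] | None = None,
    init: str = "uniform",
) -> SimulationResult:
    """Run the network for ``duration`` ms under the configured drive."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return _run(net, cfg, [(duration, cfg.theta)], seed, record, injections, init)


def ramp_drive(
    net: NetworkRealization,
    cfg: BrnConfig,
    theta_schedule: list[float],
    segment: float = 1000.0,
    seed: int = 0,
    record: RecordingSpec | None = RecordingSpec(),
) -> SimulationResult:
    """Piecewise-constant drive, one ``segment`` ms per theta value.

    Used to expose excitatory-inhibitory coupling over a range of activity
    levels (default protocol: theta from 1.5 down to 0.9 in 0.1 steps).
    """
    if not theta_schedule:
        raise ValueError("schedule must be non-empty")
    return _run(net, cfg, [(segment, th) for th in theta_schedule], seed, record)


def population_rate(raster: SpikeRaster, t0: float, t1: float, bin_ms: float = 1.0) -> np.ndarray:
    """Population-mean rate (spikes/s per neuron) in ``bin_ms`` bins."""
    edges = np.arange(t0, t1 + 1e-9, bin_ms)
    all_t = np.concatenate([t for t in raster.trains.values()]) if raster.trains else np.empty(0)
    counts, _ = np.histogram(all_t, bins=edges)
    return counts / (raster.n_neurons * bin_ms / 1000.0)


def _survival_time(
    raster: SpikeRaster, cutoff: float, rate_floor: float = 0.1, hold_ms: float = 50.0
) -> float:
    """Time from drive cutoff until the population rate first stays below
    ``rate_floor`` spikes/s for ``hold_ms``."""
    t1 = raster.duration
    rates = population_rate(raster, cutoff, t1, bin_ms=1.0)
    hold = int(hold_ms)
    if rates.size < hold:
        return t1 - cutoff
    below = rates < rate_floor
    csum = np.concatenate(([0], np.cumsum(below)))
    run = csum[hold:] - csum[:-hold]
    silent = np.flatnonzero(run == hold)
    if silent.size == 0:
        return t1 - cutoff
    return float(silent[0])


def excitability_test(
    net: NetworkRealization,
    cfg: BrnConfig,
    warmup: float = 1000.0,
    tail: float = 1000.0,
    seed: int = 0,
    record: RecordingSpec | None = None,
) -> tuple[float, SimulationResult]:
    """Switch the external drive off after ``warmup`` ms and measure how
    long network activity survives.

    Returns (survival time in ms, full simulation result).  The survival
    time saturates at ``tail`` if activity never dies out.
    """
    if warmup < 500.0:
        raise ValueError("warmup must be at least 500 ms to reach steady state")
    res = _run(net, cfg, [(warmup, cfg.theta), (tail, 0.0)], seed, record)
    n_pre = sum(
        int(((t >= warmup - 100.0) & (t < warmup)).sum()) for t in res.raster.trains.values()
    )
    if n_pre == 0:
        warnings.warn("network already silent at drive cutoff")
        return 0.0, res
    return _survival_time(res.raster, warmup), res


def self_sustained_test(
    net: NetworkRealization,
    cfg: BrnConfig,
    stim_ms: float = 50.0,
    stim_theta: float = 2.0,
    duration: float = 2000.0,
    seed: int = 0,
    record: RecordingSpec | None = None,
) -> tuple[float, SimulationResult]:
    """Brief suprathreshold stimulation, then no external input.

    Returns (mean excitatory rate over the drive-free period in spikes/s,
    simulation result); probes intrinsically sustained activity.
    """
    from .spiketrain import firing_rate

    res = _run(net, cfg, [(stim_ms, stim_theta), (duration, 0.0)], seed, record, init="rest")
    rate = firing_rate(res.raster, EXC, (stim_ms, stim_ms + duration))
    return rate, res


def parameter_scan(
    base_cfg: BrnConfig,
    k_ei_values=(1.0,),
    k_ie_values=(1.0,),
    k_ii_values=(1.0,),
    seeds=(0, 1, 2),
    duration: float = 5000.0,
    warmup: float = 500.0,
    record: RecordingSpec | None = RecordingSpec(n_vm=20),
) -> pd.DataFrame:
    """Grid scan over the synaptic scale factors.

    For each (k_ei, k_ie, k_ii) cell and each seed the network is built,
    simulated for ``warmup + duration`` ms, and the standard activity
    metrics are computed on the post-warmup window.  Diverged cells are
    flagged, not fatal.  Returns a tidy table.
    """
    from .evaluation import collect_metrics

    rows = []
    for seed in seeds:
        for k_ei in k_ei_values:
            for k_ie in k_ie_values:
                for k_ii in k_ii_values:
                    cfg = replace(base_cfg, k_ei=k_ei, k_ie=k_ie, k_ii=k_ii)
                    net = build_network(cfg, seed=seed)
                    row = {"k_ei": k_ei, "k_ie": k_ie, "k_ii": k_ii, "seed": seed}
                    try:
                        res = simulate(net, cfg, warmup + duration, seed=seed, record=record)
                        metrics = collect_metrics(res, warmup_discard=warmup)
                        row.update(metrics)
                        row["diverged"] = False
                    except SimulationDivergedError as err:
                        row["diverged"] = True
                        row["diverged_at_ms"] = err.t_ms
                    rows.append(row)
    return pd.DataFrame(rows)
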