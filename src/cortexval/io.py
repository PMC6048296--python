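"""Plain-text readers and writers for rasters, analog traces, configs,
and run manifests.

All dialects are line-oriented text so fixtures and reports diff cleanly:
rasters are two tab-separated columns (neuron id, spike time in ms) with a
sidecar label file; traces are a time column plus one column per channel;
configs are INI files with [network]/[membrane]/[synapse]/[drive]/[protocol]
sections.  A reader shim for NEST-style .gdf files (time, id order
swapped) is included.
"""

from __future__ import annotations

import configparser
import datetime
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .network import BrnConfig, SimulationResult
from .spiketrain import SpikeRaster
from .structural import MembraneParams, SynapseKernel
from .subthreshold import AnalogTrace, CURRENT_DT, VM_DT

__all__ = [
    "read_raster",
    "write_raster",
    "read_gdf",
    "read_trace",
    "write_trace",
    "config_to_ini",
    "config_from_ini",
    "RunManifest",
    "save_result",
    "load_result",
]

_KIND_DT = {"vm": VM_DT, "exc_current": CURRENT_DT, "inh_current": CURRENT_DT,
            "total_current": CURRENT_DT}
_KIND_UNITS = {"vm": "mV", "exc_current": "pA", "inh_current": "pA", "total_current": "pA"}


def _labels_path(path: Path) -> Path:
    return path.with_name(path.name + ".labels")


def write_raster(path, raster: SpikeRaster, labels_path=None) -> None:
    path = Path(path)
    labels_path = Path(labels_path) if labels_path else _labels_path(path)
    with open(path, "w") as fh:
        fh.write("# cortexval spike raster: neuron_id<TAB>time_ms\n")
        fh.write(f"# duration_ms={raster.duration}\n")
        fh.write(f"# origin={raster.origin}\n")
        for nid in sorted(raster.trains):
            for t in raster.trains[nid]:
                fh.write(f"{nid}\t{t:.6g}\n")
    with open(labels_path, "w") as fh:
        for nid in sorted(raster.labels):
            fh.write(f"{nid}\t{raster.labels[nid]}\n")


def _read_labels(labels_path: Path) -> dict[int, str]:
    labels: dict[int, str] = {}
    for lineno, line in enumerate(labels_path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1] not in ("e", "i"):
            raise ValueError(f"{labels_path}:{lineno}: malformed label line {line!r}")
        labels[int(parts[0])] = parts[1]
    return labels


def read_raster(path, labels_path=None, duration: float | None = None) -> SpikeRaster:
    """Read a two-column raster file plus its sidecar label file.

    Unsorted spike times are sorted on read with a warning.  The duration
    is taken from the header unless overridden.
    """
    path = Path(path)
    labels_path = Path(labels_path) if labels_path else _labels_path(path)
    ids, times = [], []
    origin = "recording"
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            if "duration_ms=" in line and duration is None:
                duration = float(line.split("duration_ms=")[1])
            if "origin=" in line:
                origin = line.split("origin=")[1].strip()
            continue
        if not line.strip():
            continue
        parts = line.split()
        try:
            ids.append(int(parts[0]))
            times.append(float(parts[1]))
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}:{lineno}: malformed raster line {line!r}") from err
    labels = _read_labels(labels_path)
    unknown = set(ids) - set(labels)
    if unknown:
        raise ValueError(f"{path}: neurons without label: {sorted(unknown)[:5]}")
    if duration is None:
        duration = max(times, default=0.0)
    ids_a, times_a = np.array(ids, dtype=int), np.array(times)
    for nid in set(ids):
        tt = times_a[ids_a == nid]
        if np.any(np.diff(tt) < 0):
            warnings.warn(f"{path}: spike times of neuron {nid} unsorted; sorting on read")
            break
    return SpikeRaster.from_arrays(ids_a, times_a, labels, duration, origin=origin)


def read_gdf(path, labels: dict[int, str], duration: float | None = None) -> SpikeRaster:
    """NEST-style .gdf reader: columns are (time_ms, neuron_id)."""
    path = Path(path)
    ids, times = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        try:
            times.append(float(parts[0]))
            ids.append(int(parts[1]))
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}:{lineno}: malformed gdf line {line!r}") from err
    if duration is None:
        duration = max(times, default=0.0)
    return SpikeRaster.from_arrays(np.array(ids, int), np.array(times), labels, duration,
                                   origin="simulation")


def write_trace(path, traces: list[AnalogTrace]) -> None:
    """Write one or more aligned channels: time_ms column plus one column
    per channel; a '#' header declares kind, dt, and units."""
    path = Path(path)
    kinds = {tr.kind for tr in traces}
    dts = {tr.dt for tr in traces}
    sizes = {tr.values.size for tr in traces}
    if len(kinds) != 1 or len(dts) != 1 or len(sizes) != 1:
        raise ValueError("all channels in one file must share kind, dt, and length")
    tr0 = traces[0]
    channels = ",".join(str(tr.channel_id) for tr in traces)
    header = (
        f"cortexval analog trace\nkind={tr0.kind} dt_ms={tr0.dt} "
        f"units={_KIND_UNITS.get(tr0.kind, '?')} t0_ms={tr0.t0}\nchannels={channels}"
    )
    data = np.column_stack([tr0.times()] + [tr.values for tr in traces])
    np.savetxt(path, data, fmt="%.6g", delimiter="\t", header=header)


def read_trace(path, expect_kind: str | None = None, allow_dt_mismatch: bool = False) -> list[AnalogTrace]:
    """Read a multi-channel trace file into per-channel AnalogTraces.

    The declared dt is validated against the dialect for its kind (0.1 ms
    for Vm, 0.05 ms for currents) unless ``allow_dt_mismatch`` is set, for
    external recordings on other grids.
    """
    path = Path(path)
    kind, dt, t0, channels = None, None, 0.0, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("kind="):
                    kind = tok[5:]
                elif tok.startswith("dt_ms="):
                    dt = float(tok[6:])
                elif tok.startswith("t0_ms="):
                    t0 = float(tok[6:])
                elif tok.startswith("channels="):
                    channels = tok[9:].split(",")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if kind is None or dt is None:
        raise ValueError(f"{path}: missing kind/dt header")
    if expect_kind is not None and kind != expect_kind:
        raise ValueError(f"{path}: expected kind {expect_kind!r}, found {kind!r}")
    nominal = _KIND_DT.get(kind)
    if nominal is not None and abs(dt - nominal) > 1e-9 and not allow_dt_mismatch:
        raise ValueError(
            f"{path}: dt {dt} ms does not match the {kind} dialect ({nominal} ms); "
            "pass allow_dt_mismatch=True for external recordings"
        )
    if channels is None:
        channels = [str(i) for i in range(data.shape[1] - 1)]
    out = []
    for k, ch in enumerate(channels):
        cid: int | str = int(ch) if ch.lstrip("-").isdigit() else ch
        out.append(AnalogTrace(data[:, k + 1], dt=dt, kind=kind, channel_id=cid, t0=t0))
    return out


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def config_to_ini(cfg: BrnConfig, path) -> None:
    network = {"Ne": cfg.Ne, "Ni": cfg.Ni, "g": cfg.g,
               "k_ei": cfg.k_ei, "k_ie": cfg.k_ie, "k_ii": cfg.k_ii, "name": cfg.name}
    keymap = {"p": "p", "e<-e": "p_ee", "i<-e": "p_ie", "e<-i": "p_ei", "i<-i": "p_ii"}
    for key, val in cfg.connectivity.items():
        network[keymap[key]] = val
    m = cfg.membrane
    sections = {
        "network": network,
        "membrane": {"Vth": m.Vth, "Vr": m.Vr, "Vrest": m.Vrest,
                     "tau_m": m.tau_m, "Cm": m.Cm, "tau_ref": m.tau_ref},
        "synapse": {"J": cfg.J, "tau_syn": cfg.syn.tau_syn, "delay": cfg.syn.delay},
        "drive": {"theta": cfg.theta},
        "protocol": {"dt": cfg.dt},
    }
    writer = configparser.ConfigParser()
    writer.read_dict({s: {k: str(v) for k, v in d.items()} for s, d in sections.items()})
    with open(path, "w") as fh:
        writer.write(fh)


def config_from_ini(path) -> BrnConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(path)
    net, mem, syn = cp["network"], cp["membrane"], cp["synapse"]
    if "p" in net:
        connectivity = {"p": net.getfloat("p")}
    else:
        connectivity = {"e<-e": net.getfloat("p_ee"), "i<-e": net.getfloat("p_ie"),
                        "e<-i": net.getfloat("p_ei"), "i<-i": net.getfloat("p_ii")}
    membrane = MembraneParams(
        Cm=mem.getfloat("Cm"), tau_m=mem.getfloat("tau_m"), Vrest=mem.getfloat("Vrest"),
        Vth=mem.getfloat("Vth"), Vr=mem.getfloat("Vr"), tau_ref=mem.getfloat("tau_ref"),
    )
    J = syn.getfloat("J")
    kernel = SynapseKernel(J=J, tau_syn=syn.getfloat("tau_syn"), delay=syn.getfloat("delay"))
    return BrnConfig(
        Ne=net.getint("Ne"), Ni=net.getint("Ni"), connectivity=connectivity,
        J=J, g=net.getfloat("g"),
        k_ei=net.getfloat("k_ei", 1.0), k_ie=net.getfloat("k_ie", 1.0),
        k_ii=net.getfloat("k_ii", 1.0),
        membrane=membrane, syn=kernel,
        theta=cp["drive"].getfloat("theta"),
        dt=cp["protocol"].getfloat("dt", 0.05),
        name=net.get("name", "custom"),
    )


# ---------------------------------------------------------------------------
# Run manifests and result directories
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_name: str
    seed: int
    tool_version: str = "0.1.0"
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def save_result(result: SimulationResult, out_dir) -> None:
    """Write a simulation result as raster + trace + config files with a
    manifest alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(out / "raster.txt", result.raster)
    if result.vm_traces:
        write_trace(out / "vm.txt", list(result.vm_traces.values()))
        write_trace(out / "current_e.txt", list(result.exc_current_traces.values()))
        write_trace(out / "current_i.txt", list(result.inh_current_traces.values()))
    config_to_ini(result.config, out / "config.ini")
    outputs = [p.name for p in sorted(out.iterdir()) if p.name != "manifest.json"]
    RunManifest(config_name=result.config.name, seed=result.seed,
                outputs=outputs).write(out / "manifest.json")


@dataclass
class LoadedResult:
    """File-backed stand-in for SimulationResult, accepted by the analyzers."""

    raster: SpikeRaster
    vm_traces: dict
    exc_current_traces: dict
    inh_current_traces: dict
    config: BrnConfig
    seed: int


def load_result(out_dir) -> LoadedResult:
    out = Path(out_dir)
    raster = read_raster(out / "raster.txt")
    cfg = config_from_ini(out / "config.ini")
    manifest = json.loads((out / "manifest.json").read_text())

    def _load(name, kind):
        p = out / name
        if not p.exists():
            return {}
        return {tr.channel_id: tr for tr in read_trace(p, expect_kind=kind)}

    return LoadedResult(
        raster=raster,
        vm_traces=_load("vm.txt", "vm"),
        exc_current_traces=_load("current_e.txt", "exc_current"),
        inh_current_traces=_load("current_i.txt", "inh_current"),
        config=cfg,
        seed=int(manifest["seed"]),
    )
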