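"""Criteria table and grading harness for cortical network models.

Encodes the nine validation criteria for persistently depolarized network
states (firing rate, irregularity, non-burstiness, spike-count
correlations, membrane-potential and input stability, balance,
excitability, and structural realism) and grades measured values with the
three-level tolerance scheme: green for deviations up to 20%, yellow up
to 60%, red beyond; qualitative criteria pass or fail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spiketrain import (
    EXC,
    SegmentSpec,
    burstiness_check,
    firing_rate,
    population_isi_stats,
    spike_count_correlation,
)
from .subthreshold import (
    AnalogTrace,
    UpStateInterval,
    balance_regression,
    cv_current_detrended,
    cv_vm,
    excise_spikes,
)

__all__ = [
    "Criterion",
    "CriteriaReport",
    "default_criteria",
    "grade",
    "collect_metrics",
    "evaluate_model",
    "GREEN",
    "YELLOW",
    "RED",
    "NOT_APPLICABLE",
]

GREEN, YELLOW, RED, NOT_APPLICABLE = "green", "yellow", "red", "not_applicable"
GREEN_TOL = 20.0  # % deviation
YELLOW_TOL = 60.0


@dataclass
class Criterion:
    id: int
    name: str
    kind: str  # range | point | upper | qualitative | composite
    target: object
    units: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind == "range":
            lo, hi = self.target
            if not lo < hi:
                raise ValueError("range criterion needs low < high")


def default_criteria(up_state_mode: bool = False) -> list[Criterion]:
    """The nine validation criteria with their benchmark values.

    ``up_state_mode`` switches the irregularity targets from the 5 s
    segment ranges to the Up-state point values.
    """
    irregularity = (
        {"cv_isi": ("point", 0.76), "lv_isi": ("point", 0.56)}
        if up_state_mode
        else {"cv_isi": ("range", (0.95, 1.2)), "lv_isi": ("range", (0.68, 1.2))}
    )
    return [
        Criterion(1, "firing rate", "range", (0.18, 10.0), "spikes/s",
                  "mean firing rate of excitatory neurons"),
        Criterion(2, "irregularity", "composite", irregularity, "",
                  "average CV(ISI) and LV(ISI) across neurons"),
        Criterion(3, "non-burstiness", "qualitative", "non_bursty", "",
                  "no prominent ISI peak below 10 ms"),
        Criterion(4, "correlations", "upper", 0.008, "",
                  "mean pairwise spike-count correlation (10 ms bins)"),
        Criterion(5, "membrane potential stability", "point", 0.22, "",
                  "CV(Vm) within sustained activation"),
        Criterion(6, "input stability", "point", 0.15, "",
                  "CV of detrended excitatory input current"),
        Criterion(7, "balance", "qualitative", "proportional", "",
                  "proportionality of 10 ms averaged e/i currents"),
        Criterion(8, "excitability", "composite",
                  {"survival_ms": ("threshold", (300.0, 100.0))}, "ms",
                  "activity sustained for hundreds of ms after stimulation"),
        Criterion(9, "structural realism", "composite",
                  {"psp_ee": ("range", (0.03, 0.6)),
                   "threshold_distance_ratio": ("threshold", (20.0, 10.0)),
                   "p_ee": ("point", 0.07),
                   "p_other": ("point", 0.24)}, "",
                  "PSP_e<-e range, Vth-Vrest >> PSP_e<-e, connection probabilities"),
    ]


def _deviation(measured: float, kind: str, target) -> float:
    """Percent deviation from a point target, range, or upper bound."""
    if kind == "point":
        return 100.0 * abs(measured - target) / abs(target)
    if kind == "range":
        lo, hi = target
        if lo <= measured <= hi:
            return 0.0
        bound = lo if measured < lo else hi
        return 100.0 * abs(measured - bound) / abs(bound)
    if kind == "upper":
        if measured <= target:
            return 0.0
        return 100.0 * (measured - target) / target
    raise ValueError(f"no deviation rule for kind {kind!r}")


def grade(measured, criterion: Criterion) -> tuple[str, float | None]:
    """Grade a measurement against one criterion.

    Returns (grade, percent deviation); deviation is None for qualitative
    criteria and NaN-free.  Larger deviations never grade better.
    """
    if measured is None:
        return NOT_APPLICABLE, None
    if criterion.kind == "qualitative":
        ok = bool(measured) if isinstance(measured, (bool, np.bool_)) else measured == criterion.target
        return (GREEN if ok else RED), None
    if criterion.kind == "composite":
        worst, worst_dev = GREEN, 0.0
        order = {GREEN: 0, YELLOW: 1, RED: 2}
        for key, (kind, target) in criterion.target.items():
            if key not in measured or measured[key] is None:
                return NOT_APPLICABLE, None
            if kind == "threshold":
                green_at, yellow_at = target
                v = measured[key]
                g = GREEN if v >= green_at else YELLOW if v >= yellow_at else RED
                dev = 0.0 if v >= green_at else 100.0 * (green_at - v) / green_at
            else:
                dev = _deviation(measured[key], kind, target)
                g = GREEN if dev <= GREEN_TOL else YELLOW if dev <= YELLOW_TOL else RED
            if order[g] > order[worst] or (order[g] == order[worst] and dev > worst_dev):
                worst, worst_dev = g, dev
        return worst, worst_dev
    dev = _deviation(float(measured), criterion.kind, criterion.target)
    g = GREEN if dev <= GREEN_TOL else YELLOW if dev <= YELLOW_TOL else RED
    return g, dev


@dataclass
class CriteriaReport:
    """Per-criterion measured values, targets, deviations, and grades."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        def clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return json.dumps([{k: clean(v) for k, v in r.items()} for r in self.rows], indent=2)

    def grade_of(self, criterion_id: int) -> str:
        for r in self.rows:
            if r["criterion_id"] == criterion_id:
                return r["grade"]
        raise KeyError(criterion_id)

    def __str__(self) -> str:
        lines = [f"{'#':>2} {'criterion':<32} {'measured':<24} {'dev %':>7}  grade"]
        for r in self.rows:
            m = r["measured"]
            mtxt = (
                ", ".join(f"{k}={v:.3g}" for k, v in m.items())
                if isinstance(m, dict)
                else (f"{m:.4g}" if isinstance(m, float) else str(m))
            )
            d = r["deviation_pct"]
            dtxt = f"{d:7.1f}" if d is not None else "      -"
            lines.append(f"{r['criterion_id']:>2} {r['name']:<32} {mtxt:<24.24} {dtxt}  {r['grade']}")
        return "\n".join(lines)


def collect_metrics(result, warmup_discard: float = 500.0, segment_length: float = 5000.0) -> dict:
    """Compute the criteria-1-to-7 activity metrics from one simulation.

    Analysis runs on the post-warmup window, split into 5 s segments when
    it is long enough (otherwise treated as a single segment).
    """
    raster = result.raster
    t0, t1 = warmup_discard, raster.duration
    if t1 - t0 < 1000.0:
        raise ValueError("analysis window shorter than 1 s")
    seg_len = segment_length if (t1 - t0) >= segment_length else (t1 - t0)
    segments = SegmentSpec.fixed(t1, segment_length=seg_len, t0=t0)

    out: dict = {"rate_e": firing_rate(raster, EXC, (t0, t1))}
    try:
        isi = population_isi_stats(raster, segments, min_spikes=5, population=EXC)
        out["cv_isi"], out["lv_isi"] = isi.cv, isi.lv
    except ValueError:
        out["cv_isi"] = out["lv_isi"] = None
    try:
        cc = spike_count_correlation(raster, segments, seed=result.seed)
        out["cc"] = cc.mean_cc
    except ValueError:
        out["cc"] = None
    try:
        out["burst_verdict"] = burstiness_check(raster).verdict
    except ValueError:
        out["burst_verdict"] = None

    vrest = result.config.membrane.Vrest
    cvs_vm, cvs_ie, slopes, rs = [], [], [], []
    win = UpStateInterval(start=t0, end=t1)
    for nid, vm in result.vm_traces.items():
        spikes = [t for t in result.raster.trains[nid] if t0 <= t <= t1]
        masked = excise_spikes(vm, spikes) if spikes else vm
        try:
            cvs_vm.append(cv_vm(masked, win, vrest))
        except ValueError:
            pass
    for nid, ie in result.exc_current_traces.items():
        try:
            cvs_ie.append(cv_current_detrended(ie, (t0, t1)))
        except ValueError:
            pass
        ii = result.inh_current_traces.get(nid)
        if ii is not None:
            try:
                b = balance_regression(_cut(ie, t0, t1), _cut(ii, t0, t1))
                slopes.append(b.slope)
                rs.append(b.pearson_r)
            except ValueError:
                pass
    out["cv_vm"] = float(np.mean(cvs_vm)) if cvs_vm else None
    out["cv_ie"] = float(np.mean(cvs_ie)) if cvs_ie else None
    out["balance_slope"] = float(np.mean(slopes)) if slopes else None
    out["balance_r"] = float(np.mean(rs)) if rs else None
    return out


def _cut(trace: AnalogTrace, t0: float, t1: float) -> AnalogTrace:
    i0 = max(trace.index(t0), 0)
    i1 = min(trace.index(t1), trace.values.size - 1)
    return AnalogTrace(trace.values[i0 : i1 + 1], trace.dt, trace.kind, trace.channel_id,
                       trace.t0 + i0 * trace.dt)


def balance_from_result(result, warmup_discard: float = 500.0):
    """Neuron-averaged balance regression from a simulation's recorded
    currents (typically a drive-ramp protocol, which exposes the
    proportionality over a range of activity levels)."""
    from .subthreshold import BalanceResult

    t0, t1 = warmup_discard, result.raster.duration
    slopes, rs, n_bins = [], [], 0
    for nid, ie in result.exc_current_traces.items():
        ii = result.inh_current_traces.get(nid)
        if ii is None:
            continue
        try:
            b = balance_regression(_cut(ie, t0, t1), _cut(ii, t0, t1))
        except ValueError:
            continue
        slopes.append(b.slope)
        rs.append(b.pearson_r)
        n_bins = b.n_bins
    if not slopes:
        raise ValueError("no usable current pair for balance")
    return BalanceResult(slope=float(np.mean(slopes)), pearson_r=float(np.mean(rs)),
                        n_bins=n_bins)


def _mean_or_none(values: list) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def evaluate_model(
    results: list,
    survival_ms: float | None = None,
    balance_result=None,
    structural: dict | None = None,
    warmup_discard: float = 500.0,
    up_state_mode: bool = False,
) -> CriteriaReport:
    """Grade a model against all nine criteria.

    ``results`` is a list of SimulationResult trials; metrics are averaged
    across trials before grading.  ``balance_result`` may supply a
    BalanceResult from a drive-ramp protocol (the proportionality is best
    exposed over a range of activity levels); otherwise the stationary
    per-neuron regressions are used.  ``structural`` supplies criterion-9
    facts (psp_ee in mV, threshold_distance_ratio, p_ee, p_other).
    Missing inputs leave the criterion not_applicable.
    """
    metrics = [collect_metrics(r, warmup_discard) for r in results]
    mean = lambda key: _mean_or_none([m.get(key) for m in metrics])

    verdicts = [m.get("burst_verdict") for m in metrics if m.get("burst_verdict")]
    non_bursty = None if not verdicts else all(v == "non_bursty" for v in verdicts)

    if balance_result is not None:
        balanced = balance_result.slope > 0 and balance_result.pearson_r > 0.5
    elif mean("balance_r") is not None:
        balanced = mean("balance_slope") > 0 and mean("balance_r") > 0.5
    else:
        balanced = None

    irregularity = (
        {"cv_isi": mean("cv_isi"), "lv_isi": mean("lv_isi")}
        if mean("cv_isi") is not None
        else None
    )
    measured = {
        1: mean("rate_e"),
        2: irregularity,
        3: non_bursty,
        4: mean("cc"),
        5: mean("cv_vm"),
        6: mean("cv_ie"),
        7: balanced,
        8: {"survival_ms": survival_ms} if survival_ms is not None else None,
        9: structural,
    }
    report = CriteriaReport()
    for crit in default_criteria(up_state_mode):
        g, dev = grade(measured[crit.id], crit)
        report.rows.append(
            {"criterion_id": crit.id, "name": crit.name, "measured": measured[crit.id],
             "target": crit.target, "units": crit.units, "deviation_pct": dev, "grade": g}
        )
    return report
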