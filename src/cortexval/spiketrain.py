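"""Spike-train statistics for validating persistently depolarized network states.

Implements the firing-rate, irregularity (CV and local variation of
interspike intervals), burstiness, and pairwise spike-count correlation
measures used to characterize asynchronous-irregular cortical activity,
together with the segmentation conventions (5 s segments or individual Up
states, neuron-wise minimum-spike filter, 85:15 excitatory:inhibitory
subsampling of 140 neurons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeRaster",
    "SegmentSpec",
    "IsiStats",
    "CorrelationResult",
    "BurstinessResult",
    "InsufficientSpikesError",
    "cv_isi",
    "lv_isi",
    "population_isi_stats",
    "firing_rate",
    "spike_count_correlation",
    "burstiness_check",
]

EXC = "e"
INH = "i"


class InsufficientSpikesError(ValueError):
    """Raised when a spike train has too few spikes for an ISI statistic."""


@dataclass
class SpikeRaster:
    """Parallel spike trains on a common clock.

    Parameters
    ----------
    trains
        Mapping neuron id -> sorted spike times in ms.
    labels
        Mapping neuron id -> ``"e"`` (excitatory) or ``"i"`` (inhibitory).
    duration
        Total recording/simulation duration in ms.
    origin
        ``"simulation"`` or ``"recording"``.
    """

    trains: dict[int, np.ndarray]
    labels: dict[int, str]
    duration: float
    origin: str = "simulation"

    def __post_init__(self) -> None:
        for nid, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"spike times of neuron {nid} not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(f"spike times of neuron {nid} outside [0, duration]")
            self.trains[nid] = t
        unknown = set(self.trains) - set(self.labels)
        if unknown:
            raise ValueError(f"neurons without population label: {sorted(unknown)[:5]}")

    @classmethod
    def from_arrays(
        cls,
        ids: np.ndarray,
        times: np.ndarray,
        labels: dict[int, str],
        duration: float,
        origin: str = "simulation",
    ) -> "SpikeRaster":
        """Build from two parallel columns (neuron id, spike time in ms)."""
        ids = np.asarray(ids, dtype=int)
        times = np.asarray(times, dtype=float)
        order = np.lexsort((times, ids))
        ids, times = ids[order], times[order]
        trains: dict[int, np.ndarray] = {nid: np.empty(0) for nid in labels}
        if ids.size:
            uniq, start = np.unique(ids, return_index=True)
            bounds = np.append(start, ids.size)
            for k, nid in enumerate(uniq):
                trains[int(nid)] = times[bounds[k] : bounds[k + 1]]
        return cls(trains, dict(labels), float(duration), origin)

    def neuron_ids(self, population: str | None = None) -> list[int]:
        if population is None:
            return sorted(self.labels)
        return sorted(n for n, lab in self.labels.items() if lab == population)

    @property
    def n_neurons(self) -> int:
        return len(self.labels)


@dataclass
class SegmentSpec:
    """Analysis windows: fixed-length segments or detected Up states."""

    windows: list[tuple[float, float, str]]
    segment_length: float = 5000.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, _kind in sorted(self.windows):
            if start >= end:
                raise ValueError("segment start must precede end")
            if start < prev_end:
                raise ValueError("segments overlap")
            prev_end = end

    @classmethod
    def fixed(cls, duration: float, segment_length: float = 5000.0, t0: float = 0.0) -> "SegmentSpec":
        """Tile ``[t0, duration)`` with non-overlapping fixed segments.

        A trailing remainder shorter than ``segment_length`` is dropped.
        """
        edges = np.arange(t0, duration + 1e-9, segment_length)
        windows = [(float(a), float(b), "fixed_segment") for a, b in zip(edges[:-1], edges[1:])]
        if not windows:
            raise ValueError("duration shorter than one segment")
        return cls(windows, segment_length)

    @classmethod
    def up_states(cls, intervals: list[tuple[float, float]]) -> "SegmentSpec":
        return cls([(a, b, "up_state") for a, b in intervals])


@dataclass
class IsiStats:
    """Population-averaged interspike-interval irregularity."""

    cv: float
    lv: float
    n_neurons_used: int
    per_segment: list[dict] = field(default_factory=list)


@dataclass
class CorrelationResult:
    """Mean pairwise Pearson correlation of binned spike counts."""

    mean_cc: float
    bin_width: float
    n_sampled: int
    ratio_exc_inh: tuple[int, int]
    n_pairs_used: int
    n_pairs_excluded: int = 0


@dataclass
class BurstinessResult:
    verdict: str  # "bursty" | "non_bursty"
    fraction_bursty: float
    histogram_edges: np.ndarray
    mean_histogram: np.ndarray


def cv_isi(train: np.ndarray) -> float:
    """Coefficient of variation of interspike intervals.

    Sample standard deviation (n-1 denominator) of the ISIs divided by the
    mean ISI.  Requires at least 3 spikes (2 intervals).
    """
    train = np.asarray(train, dtype=float)
    if train.size < 3:
        raise InsufficientSpikesError("cv_isi needs at least 3 spikes")
    isi = np.diff(train)
    return float(np.std(isi, ddof=1) / np.mean(isi))


def lv_isi(train: np.ndarray) -> float:
    """Local variation of interspike intervals (Shinomoto's L_V).

    Mean over consecutive interval pairs of 3(T_i - T_{i+1})^2 / (T_i + T_{i+1})^2,
    normalized by the number of interval pairs.  Less sensitive to slow rate
    modulation than the CV; equals 1 for Poisson and 3/(2k+1) for
    gamma-renewal trains of shape k.
    """
    train = np.asarray(train, dtype=float)
    if train.size < 3:
        raise InsufficientSpikesError("lv_isi needs at least 3 spikes")
    isi = np.diff(train)
    t1, t2 = isi[:-1], isi[1:]
    terms = 3.0 * (t1 - t2) ** 2 / (t1 + t2) ** 2
    return float(terms.mean())


def _segment_train(train: np.ndarray, start: float, end: float) -> np.ndarray:
    return train[(train >= start) & (train < end)]


def population_isi_stats(
    raster: SpikeRaster,
    segments: SegmentSpec,
    min_spikes: int = 5,
    population: str | None = None,
) -> IsiStats:
    """CV(ISI) and L_V(ISI) averaged across neurons, then across segments.

    Within each segment (or Up state) only neurons emitting at least
    ``min_spikes`` spikes enter the neuron average; a neuron additionally
    needs >= 3 spikes for the statistics to be defined at all.
    """
    ids = raster.neuron_ids(population)
    if not ids:
        raise ValueError("empty population")
    per_segment = []
    for start, end, kind in segments.windows:
        cvs, lvs = [], []
        for nid in ids:
            seg = _segment_train(raster.trains[nid], start, end)
            if seg.size < max(min_spikes, 3):
                continue
            cvs.append(cv_isi(seg))
            lvs.append(lv_isi(seg))
        if cvs:
            per_segment.append(
                {"start": start, "end": end, "kind": kind,
                 "cv": float(np.mean(cvs)), "lv": float(np.mean(lvs)), "n": len(cvs)}
            )
    if not per_segment:
        raise InsufficientSpikesError("no qualifying neurons in any segment")
    cv = float(np.mean([s["cv"] for s in per_segment]))
    lv = float(np.mean([s["lv"] for s in per_segment]))
    n_used = int(max(s["n"] for s in per_segment))
    return IsiStats(cv=cv, lv=lv, n_neurons_used=n_used, per_segment=per_segment)


def firing_rate(
    raster: SpikeRaster,
    population: str = EXC,
    window: tuple[float, float] | None = None,
) -> float:
    """Population-mean firing rate in spikes/s.

    Total spike count of the labeled neurons inside ``window`` divided by
    (number of neurons x window length).
    """
    ids = raster.neuron_ids(population)
    if not ids:
        raise ValueError(f"no neurons labeled {population!r}")
    if window is None:
        window = (0.0, raster.duration)
    start, end = window
    if not (0.0 <= start < end <= raster.duration + 1e-9):
        raise ValueError("window outside raster duration")
    count = sum(_segment_train(raster.trains[nid], start, end).size for nid in ids)
    return 1000.0 * count / (len(ids) * (end - start))


def _binned_counts(train: np.ndarray, start: float, end: float, bin_width: float) -> np.ndarray:
    # bins anchored at the segment start, half-open [t, t+bin); a trailing
    # partial bin is discarded
    n_bins = int(np.floor((end - start) / bin_width))
    edges = start + bin_width * np.arange(n_bins + 1)
    seg = train[(train >= start) & (train < edges[-1])]
    counts, _ = np.histogram(seg, bins=edges)
    return counts


def sample_neurons(
    raster: SpikeRaster,
    n_sample: int,
    ratio: tuple[int, int],
    rng: np.random.Generator,
) -> list[int]:
    """Draw ``n_sample`` neurons at the given exc:inh ratio (rounded).

    If the raster holds no more than ``n_sample`` neurons, all are used.
    """
    exc, inh = raster.neuron_ids(EXC), raster.neuron_ids(INH)
    if raster.n_neurons <= n_sample:
        return sorted(raster.labels)
    n_exc = int(round(n_sample * ratio[0] / (ratio[0] + ratio[1])))
    n_inh = n_sample - n_exc
    if len(exc) < n_exc or len(inh) < n_inh:
        raise ValueError("not enough neurons of each population for the requested split")
    chosen = list(rng.choice(exc, size=n_exc, replace=False)) + list(
        rng.choice(inh, size=n_inh, replace=False)
    )
    return [int(c) for c in chosen]


def spike_count_correlation(
    raster: SpikeRaster,
    segments: SegmentSpec,
    bin_width: float = 10.0,
    n_sample: int = 140,
    ratio: tuple[int, int] = (85, 15),
    seed: int | np.random.Generator | None = 0,
) -> CorrelationResult:
    """Mean pairwise Pearson correlation of 10 ms binned spike counts.

    A rate histogram is built per neuron and segment; all pairwise Pearson
    coefficients among the sampled neurons are averaged, per segment, then
    across segments.  Pairs in which either count vector has zero variance
    are excluded from the mean (and counted).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = sample_neurons(raster, n_sample, ratio, rng)
    seg_means = []
    n_pairs_used = 0
    n_excluded = 0
    for start, end, _kind in segments.windows:
        if (end - start) < 2 * bin_width:
            warnings.warn(f"segment [{start}, {end}) shorter than 2 bins; skipped")
            continue
        counts = np.array([_binned_counts(raster.trains[nid], start, end, bin_width) for nid in ids])
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.corrcoef(counts)
        iu = np.triu_indices(len(ids), k=1)
        vals = cc[iu]
        good = np.isfinite(vals)
        n_excluded += int((~good).sum())
        if good.any():
            seg_means.append(float(vals[good].mean()))
            n_pairs_used += int(good.sum())
    if not seg_means:
        raise ValueError("no segment yielded a defined correlation")
    return CorrelationResult(
        mean_cc=float(np.mean(seg_means)),
        bin_width=bin_width,
        n_sampled=len(ids),
        ratio_exc_inh=ratio,
        n_pairs_used=n_pairs_used,
        n_pairs_excluded=n_excluded,
    )


def burstiness_check(
    raster: SpikeRaster,
    threshold_isi: float = 10.0,
    hist_bin: float = 2.0,
    hist_max: float = 200.0,
    min_isis: int = 20,
) -> BurstinessResult:
    """Flag bursting from per-neuron ISI histograms.

    The criterion is the absence of a prominent peak at interspike
    intervals below ``threshold_isi``.  Operationally: a neuron is bursty
    if the global mode of its ISI histogram (2 ms bins, 0-200 ms) lies
    below the threshold; the raster is bursty if the majority (>50%) of
    neurons with at least ``min_isis`` intervals are.
    """
    edges = np.arange(0.0, hist_max + hist_bin, hist_bin)
    hists, flags = [], []
    for nid in sorted(raster.labels):
        t = raster.trains[nid]
        if t.size < 3:
            continue
        isi = np.diff(t)
        if isi.size < min_isis:
            continue
        h, _ = np.histogram(isi, bins=edges)
        hists.append(h)
        mode = edges[np.argmax(h)] + hist_bin / 2.0
        flags.append(mode < threshold_isi)
    if not flags:
        raise ValueError("no neuron with enough interspike intervals")
    frac = float(np.mean(flags))
    return BurstinessResult(
        verdict="bursty" if frac > 0.5 else "non_bursty",
        fraction_bursty=frac,
        histogram_edges=edges,
        mean_histogram=np.mean(hists, axis=0),
    )
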