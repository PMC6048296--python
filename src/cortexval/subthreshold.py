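"""Subthreshold membrane-potential and synaptic-current statistics.

Covers Up-state detection from the bimodal membrane-potential
distribution, spike excision, resting-potential estimation, the signed
coefficient of variation of the membrane potential CV(Vm), the detrended
current CV(Ie), the drift-corrected pooled current distribution with its
local-fluctuation inversion, and the excitatory-inhibitory balance
regression on 10 ms binned currents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "AnalogTrace",
    "UpStateInterval",
    "DriftModel",
    "BalanceResult",
    "UndefinedCVError",
    "detect_up_states",
    "excise_spikes",
    "estimate_resting_potential",
    "cv_vm",
    "cv_current_detrended",
    "pooled_density",
    "pooled_std",
    "solve_local_sigma",
    "time_averaged_cv",
    "balance_regression",
]

VM_DT = 0.1  # ms, membrane potential sampling interval
CURRENT_DT = 0.05  # ms, synaptic current sampling interval


class UndefinedCVError(ValueError):
    """Raised when a coefficient of variation has a vanishing denominator."""


@dataclass
class AnalogTrace:
    """Uniformly sampled analog signal (membrane potential or current).

    ``mask`` marks samples excluded from statistics (e.g. spike excision);
    it is created lazily and shares the sample grid.
    """

    values: np.ndarray
    dt: float
    kind: str = "vm"  # vm | exc_current | inh_current | total_current
    channel_id: int | str = 0
    t0: float = 0.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def index(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0) / self.dt))

    def window(self, start: float, end: float, valid_only: bool = True) -> np.ndarray:
        """Samples in [start, end] ms, optionally dropping masked ones."""
        i0 = max(self.index(start), 0)
        i1 = min(self.index(end), self.values.size - 1)
        vals = self.values[i0 : i1 + 1]
        if valid_only and self.mask is not None:
            vals = vals[~self.mask[i0 : i1 + 1]]
        return vals


@dataclass
class UpStateInterval:
    """A detected period of sustained depolarization."""

    start: float
    end: float
    vrest_estimate: float | None = None
    flanking_down_ok: bool = True

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class DriftModel:
    """Linearly decaying noisy current: I(t) ~ N(I0(t), sigma),
    I0(t) = I1 + (t/T)(I2 - I1)."""

    I1: float
    I2: float
    sigma: float
    T: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.T <= 0:
            raise ValueError("T must be positive")


@dataclass
class BalanceResult:
    slope: float
    pearson_r: float
    bin: float = 10.0
    n_bins: int = 0


# ---------------------------------------------------------------------------
# Up-state detection
# ---------------------------------------------------------------------------

def _bimodal_threshold(values: np.ndarray, bandwidth_mv: float = 1.0) -> float | None:
    """Midpoint between the two dominant modes of a KDE of the Vm samples.

    Returns None if the distribution is unimodal (no second peak of at
    least 10% of the main one separated by >= 3 mV).
    """
    sd = values.std()
    if sd < 1e-12:
        return None
    kde = stats.gaussian_kde(values, bw_method=bandwidth_mv / sd)
    grid = np.arange(values.min() - 2.0, values.max() + 2.0, 0.2)
    dens = kde(grid)
    peaks = [
        i for i in range(1, len(grid) - 1) if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if len(peaks) < 2:
        return None
    peaks = sorted(peaks, key=lambda i: dens[i], reverse=True)
    main = peaks[0]
    second = None
    for p in peaks[1:]:
        if abs(grid[p] - grid[main]) >= 3.0 and dens[p] >= 0.1 * dens[main]:
            second = p
            break
    if second is None:
        return None
    return float((grid[main] + grid[second]) / 2.0)


def detect_up_states(
    vm: AnalogTrace,
    min_up_ms: float = 400.0,
    min_down_ms: float = 150.0,
    trend_tolerance: float = 0.2,
) -> list[UpStateInterval]:
    """Detect Up states in a membrane potential trace.

    An Up state is a period of at least ``min_up_ms`` above the midpoint
    between the two modes of the (bimodal) Vm distribution, flanked on
    both sides by at least ``min_down_ms`` below it, with no substantial
    linear trend (|slope| x duration < ``trend_tolerance`` x mean
    depolarization above the Down mode).
    """
    if vm.duration < 1000.0:
        raise ValueError("trace must be at least 1 s long")
    thr = _bimodal_threshold(vm.values)
    if thr is None:
        warnings.warn("no bimodality in Vm distribution; no Up states detected")
        return []
    above = vm.values >= thr
    # run-length encode
    change = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [above.size]))  # exclusive
    runs = [(s, e, bool(above[s])) for s, e in zip(starts, ends)]
    down_level = float(np.median(vm.values[~above])) if (~above).any() else thr
    out: list[UpStateInterval] = []
    t = vm.times()
    for k, (s, e, is_up) in enumerate(runs):
        if not is_up or (e - s) * vm.dt < min_up_ms:
            continue
        prev_ok = k > 0 and (runs[k - 1][1] - runs[k - 1][0]) * vm.dt >= min_down_ms
        next_ok = k < len(runs) - 1 and (runs[k + 1][1] - runs[k + 1][0]) * vm.dt >= min_down_ms
        if not (prev_ok and next_ok):
            continue
        seg = vm.values[s:e]
        ts = t[s:e]
        slope = np.polyfit(ts, seg, 1)[0]
        depol = seg.mean() - down_level
        if depol <= 0 or abs(slope) * (ts[-1] - ts[0]) >= trend_tolerance * depol:
            continue
        out.append(UpStateInterval(start=float(t[s]), end=float(t[e - 1] + vm.dt)))
    return out


def excise_spikes(vm: AnalogTrace, spike_peaks: list[float], window: float = 10.0) -> AnalogTrace:
    """Mask samples within ``window`` ms centered at each spike peak.

    The mask is inclusive of both grid endpoints (101 samples for a 10 ms
    window at dt = 0.1 ms); overlapping windows merge silently.  Returns a
    new trace sharing the sample values, with the mask set.
    """
    mask = np.zeros(vm.values.size, dtype=bool) if vm.mask is None else vm.mask.copy()
    half = window / 2.0
    for peak in spike_peaks:
        if peak < vm.t0 or peak > vm.t0 + vm.duration:
            raise ValueError(f"spike peak {peak} ms outside trace")
        i0 = max(int(np.ceil((peak - half - vm.t0) / vm.dt - 1e-9)), 0)
        i1 = min(int(np.floor((peak + half - vm.t0) / vm.dt + 1e-9)), vm.values.size - 1)
        mask[i0 : i1 + 1] = True
    return AnalogTrace(vm.values, vm.dt, vm.kind, vm.channel_id, vm.t0, mask)


def estimate_resting_potential(vm: AnalogTrace, up: UpStateInterval) -> float:
    """Mean Vm in the 50-100 ms window before the Up-state transition."""
    lo, hi = up.start - 100.0, up.start - 50.0
    if lo < vm.t0:
        warnings.warn("insufficient pre-Up interval; using global Down-state mean")
        thr = _bimodal_threshold(vm.values)
        vals = vm.values if thr is None else vm.values[vm.values < thr]
        return float(vals.mean())
    vals = vm.window(lo, hi)
    return float(vals.mean())


def cv_vm(vm: AnalogTrace, up: UpStateInterval, vrest: float) -> float:
    """Signed coefficient of variation of Vm in an Up state.

    CV[Vm] = std(Vm) / (mean(Vm) - Vrest).  The sign is kept: strongly
    fluctuating networks can have a mean membrane potential below rest,
    giving a negative CV.
    """
    vals = vm.window(up.start, up.end)
    if vals.size < 2:
        raise ValueError("no valid samples in Up state")
    denom = vals.mean() - vrest
    if abs(denom) < 1e-12:
        raise UndefinedCVError("mean membrane potential equals Vrest")
    return float(vals.std() / denom)


# ---------------------------------------------------------------------------
# Synaptic current fluctuations and the drift correction
# ---------------------------------------------------------------------------

def cv_current_detrended(current: AnalogTrace, window: tuple[float, float] | None = None) -> float:
    """CV of a synaptic current after removing its linear trend.

    Ordinary least squares over the window; CV = std(residual) / mean(raw).
    """
    if window is None:
        window = (current.t0, current.t0 + current.duration)
    if window[1] - window[0] < 100.0:
        raise ValueError("analysis window must be at least 100 ms")
    i0 = max(current.index(window[0]), 0)
    i1 = min(current.index(window[1]), current.values.size - 1)
    vals = current.values[i0 : i1 + 1]
    if current.mask is not None:
        keep = ~current.mask[i0 : i1 + 1]
        vals = vals[keep]
        t = (current.t0 + current.dt * np.arange(i0, i1 + 1))[keep]
    else:
        t = current.t0 + current.dt * np.arange(i0, i1 + 1)
    mean = vals.mean()
    if abs(mean) < 1e-6:
        raise UndefinedCVError("mean current vanishes; CV undefined")
    coef = np.polyfit(t, vals, 1)
    resid = vals - np.polyval(coef, t)
    return float(resid.std() / mean)


def pooled_density(I: np.ndarray | float, model: DriftModel) -> np.ndarray | float:
    """Density of a noisy current pooled over a linear mean drift.

    P(I) = [erf((I2-I)/(sigma*sqrt2)) - erf((I1-I)/(sigma*sqrt2))] / (2(I2-I1));
    the sigma -> 0 limit is the uniform density on [min(I1,I2), max(I1,I2)].
    """
    I1, I2, sigma = model.I1, model.I2, model.sigma
    if I1 == I2:
        raise ValueError("I1 must differ from I2 (no drift: use a plain normal)")
    I = np.asarray(I, dtype=float)
    lo, hi = min(I1, I2), max(I1, I2)
    if sigma == 0.0:
        out = np.where((I >= lo) & (I <= hi), 1.0 / (hi - lo), 0.0)
        return out if out.ndim else float(out)
    s = sigma * np.sqrt(2.0)
    out = (special.erf((I2 - I) / s) - special.erf((I1 - I) / s)) / (2.0 * (I2 - I1))
    return out if out.ndim else float(out)


def pooled_std(model: DriftModel) -> float:
    """Standard deviation of the pooled distribution, by quadrature."""
    I1, I2, sigma = model.I1, model.I2, model.sigma
    lo, hi = min(I1, I2) - 10 * sigma - 1.0, max(I1, I2) + 10 * sigma + 1.0
    mean = (I1 + I2) / 2.0
    var, _ = integrate.quad(
        lambda x: (x - mean) ** 2 * pooled_density(x, model), lo, hi, limit=200
    )
    return float(np.sqrt(var))


def solve_local_sigma(overall_std: float, I1: float, I2: float, T: float = 1000.0) -> float:
    """Local fluctuation width sigma whose pooled distribution has the
    observed overall standard deviation.

    Root-finds on sigma using the quadrature standard deviation of the
    pooled density; by the variance decomposition this must agree with
    sqrt(overall_std^2 - (I2-I1)^2/12).
    """
    drift_var = (I2 - I1) ** 2 / 12.0
    if np.isclose(overall_std**2, drift_var, rtol=1e-12, atol=0.0):
        return 0.0
    if overall_std**2 < drift_var:
        raise ValueError(
            "inconsistent inputs: overall variance below the drift-only variance"
        )
    if I1 == I2:
        return float(overall_std)
    closed = float(np.sqrt(overall_std**2 - drift_var))
    f = lambda s: pooled_std(DriftModel(I1, I2, s, T)) - overall_std
    sigma = optimize.brentq(f, max(1e-9, 0.5 * closed), 2.0 * closed + 1.0, xtol=1e-8)
    if not np.isclose(sigma, closed, rtol=1e-4):
        raise RuntimeError("numerical inversion disagrees with variance decomposition")
    return float(sigma)


def time_averaged_cv(sigma: float, I1: float, I2: float) -> float:
    """Time-averaged CV of a current fluctuating around a linear decay:
    <sigma/mu> = sigma/(I2-I1) * ln(I2/I1), with the continuous limit
    sigma/I1 as I2 -> I1."""
    if I1 <= 0 or I2 <= 0:
        raise ValueError("currents must be positive (logarithm undefined)")
    if abs(I2 - I1) < 1e-6 * abs(I1):
        return float(sigma / I1)
    return float(sigma / (I2 - I1) * np.log(I2 / I1))


# ---------------------------------------------------------------------------
# Excitatory-inhibitory balance
# ---------------------------------------------------------------------------

def balance_regression(
    exc: AnalogTrace, inh: AnalogTrace, bin_width: float = 10.0
) -> BalanceResult:
    """Proportionality of 10 ms averaged excitatory and inhibitory currents.

    Both currents are averaged in non-overlapping ``bin_width`` windows;
    magnitudes are used (inhibitory currents sign-flipped), and the
    least-squares slope of |inh| on |exc| plus the Pearson r are returned.
    """
    if abs(exc.dt - inh.dt) > 1e-12 or exc.values.size != inh.values.size:
        raise ValueError("traces must share duration and sampling grid")
    per_bin = int(round(bin_width / exc.dt))
    n_bins = exc.values.size // per_bin
    if n_bins < 3:
        raise ValueError("need at least 3 bins for a balance estimate")
    e = np.abs(exc.values[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1))
    i = np.abs(inh.values[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1))
    if e.std() < 1e-12 or i.std() < 1e-12:
        raise ValueError("degenerate balance input: zero variance")
    slope, _intercept = np.polyfit(e, i, 1)
    r = float(np.corrcoef(e, i)[0, 1])
    return BalanceResult(slope=float(slope), pearson_r=r, bin=bin_width, n_bins=n_bins)
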