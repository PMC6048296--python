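"""Seeded generators of synthetic inputs with known ground truth.

Each generator emulates one statistical structure the analyzers must
recover: gamma-renewal spike trains (known CV and local variation),
common-source thinned trains (known pairwise count correlation), Up/Down
telegraph membrane potentials with Ornstein-Uhlenbeck noise (known CV(Vm)
and state boundaries), and linearly drifting noisy currents (known local
fluctuation width).  They make every metric testable without running a
network simulation or downloading recordings.
"""

from __future__ import annotations

import numpy as np

from .spiketrain import EXC, INH, SpikeRaster
from .subthreshold import AnalogTrace, UpStateInterval

__all__ = [
    "gamma_raster",
    "common_source_raster",
    "updown_vm",
    "drifting_current",
]


def _labels(n: int, exc_fraction: float = 0.85) -> dict[int, str]:
    n_exc = int(round(exc_fraction * n))
    return {i: (EXC if i < n_exc else INH) for i in range(n)}


def gamma_raster(
    n_neurons: int,
    rate: float,
    shape: float,
    duration: float,
    seed: int = 0,
    exc_fraction: float = 0.85,
) -> SpikeRaster:
    """Independent gamma-renewal spike trains.

    ``rate`` in spikes/s, ``duration`` in ms.  Expected CV(ISI) = 1/sqrt(k)
    and LV(ISI) = 3/(2k+1) for shape k; shape 1 is Poisson.
    """
    if rate * duration / 1000.0 < 10:
        raise ValueError("expected spike count below 10; raise rate or duration")
    rng = np.random.default_rng(seed)
    mean_isi = 1000.0 / rate  # ms
    n_draw = int(duration / mean_isi * 1.5) + 30
    trains = {}
    for nid in range(n_neurons):
        isis = rng.gamma(shape, scale=mean_isi / shape, size=n_draw)
        t = np.cumsum(isis)
        while t[-1] < duration:
            extra = rng.gamma(shape, scale=mean_isi / shape, size=n_draw)
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        trains[nid] = t[t < duration]
    return SpikeRaster(trains, _labels(n_neurons, exc_fraction), duration, origin="simulation")


def common_source_raster(
    n_neurons: int,
    mother_rate: float,
    p: float,
    duration: float,
    seed: int = 0,
    exc_fraction: float = 0.85,
) -> SpikeRaster:
    """Spike trains thinned independently from one Poisson mother train.

    Every neuron keeps each mother event with probability ``p``; the
    expected pairwise spike-count correlation between any two trains is
    exactly ``p`` at any bin width.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("thinning probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(mother_rate * duration / 1000.0)
    mother = np.sort(rng.random(n_events) * duration)
    trains = {
        nid: mother[rng.random(n_events) < p] for nid in range(n_neurons)
    }
    return SpikeRaster(trains, _labels(n_neurons, exc_fraction), duration, origin="simulation")


def updown_vm(
    n_states: int,
    up_ms: float = 600.0,
    down_ms: float = 300.0,
    v_up: float = -55.0,
    v_down: float = -70.0,
    noise_sd: float = 1.0,
    dt: float = 0.1,
    seed: int = 0,
    ou_tau: float = 10.0,
) -> tuple[AnalogTrace, list[UpStateInterval]]:
    """Telegraph Up/Down membrane potential with OU noise.

    The noise is an Ornstein-Uhlenbeck process with correlation time
    ``ou_tau`` ms and stationary standard deviation ``noise_sd`` (white
    noise at 0.1 ms sampling would inflate sample CV estimates beyond
    anything physiological).  Ground-truth CV(Vm) of an Up state is
    noise_sd / (v_up - v_down).  Returns the trace and the true intervals.
    """
    rng = np.random.default_rng(seed)
    n_up, n_down = int(round(up_ms / dt)), int(round(down_ms / dt))
    levels = [np.full(n_down, v_down)]
    intervals = []
    t = down_ms
    for _ in range(n_states):
        levels.append(np.full(n_up, v_up))
        # end one sample early: window queries are endpoint-inclusive
        intervals.append(UpStateInterval(start=t, end=t + up_ms - dt, vrest_estimate=v_down))
        levels.append(np.full(n_down, v_down))
        t += up_ms + down_ms
    base = np.concatenate(levels)
    if noise_sd > 0:
        from scipy.signal import lfilter

        a = np.exp(-dt / ou_tau)
        innov = noise_sd * np.sqrt(1.0 - a * a) * rng.standard_normal(base.size)
        x0 = noise_sd * rng.standard_normal()
        noise, _ = lfilter([1.0], [1.0, -a], innov, zi=np.array([a * x0]))
        base = base + noise
    return AnalogTrace(base, dt=dt, kind="vm"), intervals


def drifting_current(
    I1: float,
    I2: float,
    sigma: float,
    T: float,
    dt: float = 0.05,
    seed: int = 0,
) -> AnalogTrace:
    """Noisy current around a linearly decaying mean.

    Samples I0(t) + N(0, sigma) with I0 running linearly from I1 to I2
    over T ms.  The pooled sample distribution converges to the
    erf-difference closed form, with overall variance
    sigma^2 + (I2-I1)^2/12.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(T / dt))
    t = dt * np.arange(n)
    mean_path = I1 + t / T * (I2 - I1)
    vals = mean_path + (sigma * rng.standard_normal(n) if sigma > 0 else 0.0)
    return AnalogTrace(vals, dt=dt, kind="exc_current")
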