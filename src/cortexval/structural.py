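"""Closed-form structural calculators for cortical microcircuits.

Driving-force scaling of synaptic currents, the LIF beta-function PSP and
its peak, the shunting factor from a reduced membrane time constant, the
effective-PSP reduction cascade for active networks in vivo, the sphere
radius holding a given neuron count, and the volume-averaged
distance-dependent connection probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "MembraneParams",
    "SynapseKernel",
    "SpatialModel",
    "ReductionCascade",
    "driving_force_factor",
    "psp_time_course",
    "psp_peak_time",
    "psp_max",
    "psc_for_psp",
    "shunting_factor",
    "epsp_reduction_cascade",
    "sphere_radius",
    "mean_connection_probability",
    "mc_connection_probability",
    "benchmark_probabilities",
]


@dataclass
class MembraneParams:
    """LIF membrane parameters (capacitance pF, time constants ms, potentials mV)."""

    Cm: float = 100.0
    tau_m: float = 20.0
    Vrest: float = 0.0
    Vth: float = 20.0
    Vr: float = 10.0
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        if min(self.Cm, self.tau_m) <= 0 or self.tau_ref < 0:
            raise ValueError("Cm, tau_m must be positive; tau_ref non-negative")
        if self.Vth <= self.Vr:
            raise ValueError("Vth must exceed Vr")


@dataclass
class SynapseKernel:
    """Exponential postsynaptic current: I(t) = J exp(-t/tau_syn)."""

    J: float = 6.3  # pA
    tau_syn: float = 5.0  # ms
    delay: float = 1.5  # ms

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")


@dataclass
class SpatialModel:
    """Gaussian distance-dependent connectivity in a spherical volume."""

    P0: float = 1.0
    lam: float = 160.0  # um, Gaussian decay scale
    R: float = 270.0  # um, sphere radius
    density: float = 70000.0  # neurons per mm^3

    def __post_init__(self) -> None:
        if not 0.0 <= self.P0 <= 1.0:
            raise ValueError("P0 must be a probability")
        if min(self.lam, self.R, self.density) <= 0:
            raise ValueError("lam, R, density must be positive")


@dataclass
class ReductionCascade:
    driving_factor: float
    shunting_factor: float
    calcium_factor: float = 0.31

    def __post_init__(self) -> None:
        for f in (self.driving_factor, self.shunting_factor, self.calcium_factor):
            if not 0.0 < f <= 1.0:
                raise ValueError("each reduction factor must lie in (0, 1]")

    @property
    def combined(self) -> float:
        return self.driving_factor * self.shunting_factor * self.calcium_factor


def driving_force_factor(Esyn: float, Vrest: float, Vdep: float) -> float:
    """Current (and PSP) reduction from the shrunken driving force at a
    depolarized potential: I1/I0 = (Esyn - Vdep) / (Esyn - Vrest)."""
    if Esyn == Vrest:
        raise ValueError("driving force at rest vanishes; factor undefined")
    return (Esyn - Vdep) / (Esyn - Vrest)


def psp_time_course(mp: MembraneParams, syn: SynapseKernel, t: np.ndarray | float):
    """Beta-function PSP of a LIF neuron for an exponential PSC.

    PSP(t) = J/Cm * [exp(-t/tau_syn) - exp(-t/tau_m)] / (1/tau_m - 1/tau_syn);
    the tau_syn = tau_m limit is the alpha function (J/Cm) t exp(-t/tau).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tm, ts = mp.tau_m, syn.tau_syn
    if np.isclose(tm, ts, rtol=1e-12):
        out = (syn.J / mp.Cm) * t * np.exp(-t / tm)
    else:
        out = (syn.J / mp.Cm) * (np.exp(-t / ts) - np.exp(-t / tm)) / (1.0 / tm - 1.0 / ts)
    return out if out.ndim else float(out)


def psp_peak_time(mp: MembraneParams, syn: SynapseKernel) -> float:
    """Analytic argmax of the beta-function PSP."""
    tm, ts = mp.tau_m, syn.tau_syn
    if np.isclose(tm, ts, rtol=1e-12):
        return float(tm)
    return float(np.log(tm / ts) * tm * ts / (tm - ts))


def psp_max(mp: MembraneParams, syn: SynapseKernel) -> float:
    """Peak PSP amplitude: the beta function evaluated at its argmax."""
    return float(psp_time_course(mp, syn, psp_peak_time(mp, syn)))


def psc_for_psp(target_psp: float, mp: MembraneParams, syn: SynapseKernel) -> float:
    """PSC amplitude J producing a given peak PSP (the peak is linear in J)."""
    if target_psp <= 0:
        raise ValueError("target PSP must be positive")
    unit = psp_max(mp, SynapseKernel(J=1.0, tau_syn=syn.tau_syn, delay=syn.delay))
    return float(target_psp / unit)


def shunting_factor(tau_m_rest: float, tau_m_active: float, tau_syn: float) -> float:
    """PSP peak ratio when the membrane time constant drops from its
    resting to its active-network value (same J and Cm)."""
    if min(tau_m_rest, tau_m_active, tau_syn) <= 0:
        raise ValueError("time constants must be positive")
    syn = SynapseKernel(J=1.0, tau_syn=tau_syn)
    mk = lambda tm: MembraneParams(tau_m=tm)
    return psp_max(mk(tau_m_active), syn) / psp_max(mk(tau_m_rest), syn)


def epsp_reduction_cascade(
    driving: float, shunting: float, calcium: float = 0.31
) -> ReductionCascade:
    """Multiplicative reduction of the effective excitatory PSP in active
    networks in vivo: driving force x shunting x low-calcium release."""
    return ReductionCascade(driving, shunting, calcium)


def sphere_radius(n_neurons: float, density: float = 70000.0) -> float:
    """Radius (um) of the sphere holding ``n_neurons`` at ``density``/mm^3."""
    if n_neurons <= 0 or density <= 0:
        raise ValueError("inputs must be positive")
    volume_mm3 = n_neurons / density
    return 1000.0 * (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _angle_integral(ri: np.ndarray, rj: np.ndarray, lam: float) -> np.ndarray:
    # inner integral over alpha on [0, pi] by fixed-order Gauss-Legendre
    x, w = np.polynomial.legendre.leggauss(64)
    a = 0.5 * np.pi * (x + 1.0)
    d2 = ri[..., None] ** 2 + rj[..., None] ** 2 - 2.0 * np.cos(a) * ri[..., None] * rj[..., None]
    return 0.5 * np.pi * (np.exp(-d2 / (2.0 * lam**2)) * w).sum(axis=-1)


def mean_connection_probability(sm: SpatialModel) -> float:
    """Volume-averaged Gaussian connection probability in a sphere.

    <P> = 9 P0/(pi R^6) * triple integral of
    exp(-(ri^2 + rj^2 - 2 cos(a) ri rj)/(2 lam^2)) ri^2 rj^2 dri drj da,
    with radial densities ~ r^2 and a uniform angle density 1/pi on [0, pi].
    Evaluated by 64-point Gauss-Legendre cubature in all three variables;
    approaches P0 as lam -> infinity (kernel -> 1) and as R -> 0.
    """
    x, w = np.polynomial.legendre.leggauss(64)
    r = 0.5 * sm.R * (x + 1.0)
    wr = 0.5 * sm.R * w
    inner = _angle_integral(r[:, None].repeat(r.size, 1), r[None, :].repeat(r.size, 0), sm.lam)
    integrand = inner * (r[:, None] ** 2) * (r[None, :] ** 2)
    triple = float((wr[:, None] * wr[None, :] * integrand).sum())
    return 9.0 * sm.P0 / (np.pi * sm.R**6) * triple


def mc_connection_probability(
    sm: SpatialModel, n_samples: int = 1_000_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo estimate of the volume-averaged connection probability.

    Samples the same densities as the analytic average: radii with density
    3r^2/R^3 and the inter-somatic angle uniform on [0, pi].  Returns
    (estimate, standard error); serves as an independent check of the
    cubature in :func:`mean_connection_probability`.
    """
    rng = np.random.default_rng(seed)
    ri = sm.R * rng.random(n_samples) ** (1.0 / 3.0)
    rj = sm.R * rng.random(n_samples) ** (1.0 / 3.0)
    a = np.pi * rng.random(n_samples)
    d2 = ri**2 + rj**2 - 2.0 * np.cos(a) * ri * rj
    vals = sm.P0 * np.exp(-d2 / (2.0 * sm.lam**2))
    return float(vals.mean()), float(vals.std() / np.sqrt(n_samples))


def benchmark_probabilities(
    R: float = 270.0, lam: float = 160.0, p0_ee: float = 0.2, p0_other: float = 0.7
) -> dict[str, float]:
    """Benchmark volume-averaged connection probabilities for a 6,000-neuron
    network: zero-distance probabilities 0.2 (e<-e) and 0.7 (others),
    averaged over a 270 um sphere with a 160 um Gaussian decay, rounded to
    2 decimals."""
    frac = mean_connection_probability(SpatialModel(P0=1.0, lam=lam, R=R))
    return {
        "e<-e": round(frac * p0_ee, 2),
        "e<-i": round(frac * p0_other, 2),
        "i<-e": round(frac * p0_other, 2),
        "i<-i": round(frac * p0_other, 2),
    }
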