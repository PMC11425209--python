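"""Work, free-energy and force analysis of detected turnover events.

A rectangular Δλ event of amplitude A corresponds to the sensor doing work
on the enzyme as its atoms move through the hotspot field gradient. Per
event the molar work is

    w = λ0·P·N_A·(1 − √(1 − S̄))·A / (π·c·δλ̄)

which is the closed form of the chain: Δλ → frequency shift Δν = −c·Δλ/λ0²
→ energy N_in·h·|Δν| with the intracavity photon number N_in = a·4Pλ0/(κhc),
a = (1−√(1−S̄))/2, κ = 2πc·δλ̄/λ0². A sample of μ such work values yields
the Jarzynski free-energy penalty ΔG = (1/β)·ln⟨exp(βw)⟩, the per-intensity
mean work gives the response slope Δw/ΔI, and with the sphere-equivalent
enzyme diameter d̄E the slope converts to a trap stiffness
T_S = (Δw/ΔI)/(d̄E·N_A) and apparent force F = T_S·I, the optical-tweezer
analogue of this sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .config import SensorConfig
from .constants import CODATA

#: Display scale for trap stiffness when the slope is given in
#: J cm² MW⁻¹ mol⁻¹: T_S is then naturally of order 1e-15 N cm² MW⁻¹.
STIFFNESS_SCALE = 1e-15


# --------------------------------------------------------------------------
# per-event work
# --------------------------------------------------------------------------

@dataclass
class WorkSample:
    """Per-event molar work values w = (w_1 … w_μ) in J mol⁻¹."""

    w: np.ndarray
    events: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if self.w.size < 1:
            raise ValueError("a work sample needs at least one value")

    @property
    def mu(self) -> int:
        """Sample size μ."""
        return self.w.size

    @property
    def state_energies(self) -> np.ndarray:
        """Per-molecule state-energy differences ΔE_i = w_i/N_A (J)."""
        return self.w / CODATA.N_A

    @property
    def mean(self) -> float:
        return float(self.w.mean())

    @property
    def sem(self) -> float:
        """Standard error of the mean (0 for a single value)."""
        if self.mu < 2:
            return 0.0
        return float(self.w.std(ddof=1) / math.sqrt(self.mu))


def work_per_event(A: float, config: SensorConfig, *, signed: bool = False) -> float:
    """Molar work done by the sensor during one event of amplitude A.

    w = λ0·P·N_A·(1 − √(1 − S̄))·A / (π·c·δλ̄), in J mol⁻¹.

    By default the amplitude magnitude is used, so work is positive for
    events of either sign (red shifts are the physical convention);
    ``signed=True`` keeps the sign of A for research use.
    """
    if config.dlambda_bar <= 0:
        raise ValueError("mean linewidth must be positive")
    amp = A if signed else abs(A)
    return (
        config.lambda0
        * config.P
        * CODATA.N_A
        * (1.0 - math.sqrt(1.0 - config.S_bar))
        * amp
        / (math.pi * CODATA.c * config.dlambda_bar)
    )


def work_sample_from_events(events: Sequence, config: SensorConfig) -> WorkSample:
    """Convert detected events' amplitudes to a :class:`WorkSample`."""
    w = np.array([work_per_event(e.amplitude, config) for e in events])
    return WorkSample(w=w, events=list(events))


# --------------------------------------------------------------------------
# Jarzynski estimator
# --------------------------------------------------------------------------

@dataclass
class JarzynskiEstimate:
    """Free-energy penalty from a nonequilibrium work sample.

    ``dG`` is the asymptotic estimator (1/β)·ln m_w with
    m_w = ⟨exp(βw)⟩ over the μ per-molecule work values, re-expressed in
    J mol⁻¹; ``sigma_dG`` its Monte-Carlo propagation error
    (1/β)·(1/μ)·σ_w/m_w.
    """

    dG: float  # J mol⁻¹
    sigma_dG: float  # J mol⁻¹
    m_w: float  # exponential mean (dimensionless)
    sigma_w: float  # Monte-Carlo spread of exp(βw) (dimensionless)
    beta: float  # per-molecule inverse thermal energy 1/(k_B·T) (J⁻¹)
    T: float  # K
    mu: int


def jarzynski_estimate(
    sample: WorkSample, T: float = 298.15, *, as_printed: bool = False
) -> JarzynskiEstimate:
    """Jarzynski free-energy penalty ΔG = (1/β)·ln⟨exp(βw)⟩ from work values.

    Molar work values are converted to per-molecule energies (w/N_A) before
    applying β = 1/(k_B·T) — equivalently, molar values are used with R·T —
    and the result is returned in J mol⁻¹. Exponentials are evaluated in
    shifted (log-sum-exp) arithmetic so large βw cannot overflow.

    By Jensen's inequality ΔG ≥ mean(w), with equality only for a
    degenerate (constant) sample.

    Parameters
    ----------
    as_printed : use σ_w² = m_w² + ⟨exp(2βw)⟩ (a sum of positive terms)
        instead of the default Monte-Carlo variance
        σ_w² = ⟨exp(2βw)⟩ − m_w².
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    mu = sample.mu
    RT = CODATA.R * T  # molar 1/β
    x = sample.w / RT  # βw per event (dimensionless)
    s = float(np.max(x))
    m_sh = float(np.mean(np.exp(x - s)))  # m_w·e^{-s}
    e2_sh = float(np.mean(np.exp(2.0 * (x - s))))  # ⟨exp(2βw)⟩·e^{-2s}
    log_m_w = s + math.log(m_sh)
    dG = RT * log_m_w

    ratio_sq = e2_sh / m_sh**2  # ⟨e^{2βw}⟩ / m_w², shift-free
    if as_printed:
        sigma_ratio = math.sqrt(1.0 + ratio_sq)
    else:
        sigma_ratio = math.sqrt(max(ratio_sq - 1.0, 0.0))
    sigma_dG = RT * sigma_ratio / mu

    return JarzynskiEstimate(
        dG=dG,
        sigma_dG=sigma_dG,
        m_w=math.exp(log_m_w) if log_m_w < 700 else math.inf,
        sigma_w=sigma_ratio * (math.exp(log_m_w) if log_m_w < 700 else math.inf),
        beta=1.0 / (CODATA.k_B * T),
        T=T,
        mu=mu,
    )


# --------------------------------------------------------------------------
# work–intensity response
# --------------------------------------------------------------------------

@dataclass
class IntensityResponse:
    """Linear response of mean event work to hotspot intensity.

    ``points`` holds one (I, w̄, SE, n) tuple per dataset; the slope Δw/ΔI
    is a weighted (1/SE²) least-squares estimate with a t-based 95%
    confidence interval on n−2 degrees of freedom. When the slope is in
    J cm² MW⁻¹ mol⁻¹ (I in MW cm⁻²) it is directly comparable across
    sensors and analytes.
    """

    points: list[tuple[float, float, float, int]] = field(default_factory=list)
    slope: float = float("nan")
    intercept: float = float("nan")
    slope_se: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))

    def contains(self, slope: float) -> bool:
        lo, hi = self.ci95
        return lo <= slope <= hi


def fit_work_vs_intensity(
    datasets: Sequence[tuple[float, WorkSample]]
) -> IntensityResponse:
    """Weighted least-squares fit of mean work on intensity.

    Each dataset contributes its mean work and standard error; weights are
    1/SE². If every dataset has zero SE (e.g. exact points), an unweighted
    fit is used; a mixture of zero and non-zero SEs is rejected as
    degenerate.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 intensities to fit a slope")
    I = np.array([d[0] for d in datasets], dtype=float)
    if np.unique(I).size < 2:
        raise ValueError("need at least 2 distinct intensities")
    wbar = np.array([d[1].mean for d in datasets])
    se = np.array([d[1].sem for d in datasets])
    n = np.array([d[1].mu for d in datasets])

    if np.all(se == 0):
        weights = np.ones_like(se)
    elif np.any(se == 0):
        raise ValueError("degenerate weights: some datasets have zero variance")
    else:
        weights = 1.0 / se**2

    X = sm.add_constant(I)
    fit = sm.WLS(wbar, X, weights=weights).fit()
    ci = fit.conf_int(alpha=0.05)
    return IntensityResponse(
        points=[(float(i), float(w), float(s), int(k)) for i, w, s, k in zip(I, wbar, se, n)],
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        ci95=(float(ci[1][0]), float(ci[1][1])),
    )


# --------------------------------------------------------------------------
# mechanics: diameter, trap stiffness, force
# --------------------------------------------------------------------------

@dataclass
class MechanicalModel:
    """Optical-tweezer analogue of the sensor acting on one enzyme."""

    slope: float  # Δw/ΔI (units as supplied, typically J cm² MW⁻¹ mol⁻¹)
    V_mol: float  # molecular volume (m³)
    d_E: float  # sphere-equivalent diameter (m)
    T_S: float  # trap stiffness, slope/(d_E·N_A)

    @property
    def stiffness_mantissa(self) -> float:
        """T_S on the 10⁻¹⁵ N cm² MW⁻¹ scale (for slopes in J cm² MW⁻¹ mol⁻¹)."""
        return self.T_S / STIFFNESS_SCALE

    def force(self, I: float) -> float:
        """Apparent force F = T_S·I at hotspot intensity I."""
        return self.T_S * I


def equivalent_diameter(V_mol: float) -> float:
    """Sphere-equivalent diameter d̄E = (6V/π)^{1/3} of a molecular volume."""
    if V_mol <= 0:
        raise ValueError("molecular volume must be positive")
    return (6.0 * V_mol / math.pi) ** (1.0 / 3.0)


def trap_stiffness(slope: float, d_E: float) -> float:
    """Trap stiffness T_S = (Δw/ΔI)/(d̄E·N_A): force per unit intensity.

    The molar work slope divided by the distance over which the force acts
    (the enzyme diameter) and by N_A gives force per single enzyme per
    intensity. T_S inherits the slope's area/power units: a slope in
    J cm² MW⁻¹ mol⁻¹ yields T_S in N cm² MW⁻¹, of magnitude ~1e-15
    (see :data:`STIFFNESS_SCALE`).
    """
    if slope < 0:
        raise ValueError("slope must be non-negative")
    if d_E <= 0:
        raise ValueError("diameter must be positive")
    return slope / (d_E * CODATA.N_A)


def apparent_force(slope: float, I: float, d_E: float) -> float:
    """Apparent optical force F = (Δw/ΔI)·I/(d̄E·N_A) = T_S·I (N).

    With the slope in J cm² MW⁻¹ mol⁻¹ and I in MW cm⁻², the area/power
    units cancel and F is in newtons.
    """
    if I < 0:
        raise ValueError("intensity must be non-negative")
    return trap_stiffness(slope, d_E) * I


def mechanical_model(slope: float, V_mol: float) -> MechanicalModel:
    """Bundle slope + molecular volume into a :class:`MechanicalModel`."""
    d_E = equivalent_diameter(V_mol)
    return MechanicalModel(slope=slope, V_mol=V_mol, d_E=d_E, T_S=trap_stiffness(slope, d_E))


# --------------------------------------------------------------------------
# energy budget
# --------------------------------------------------------------------------

@dataclass
class EnergyBudget:
    """Total free energy of closing under the sensor's penalty.

    ``dG_system = dG_C + dG_pT``: the intrinsic open→closed free energy
    (negative when closing is favourable) plus the sensor's positive
    penalty. Turnover is thermodynamically feasible only while the sum
    stays negative.
    """

    dG_C: float  # J mol⁻¹
    dG_pT: float  # J mol⁻¹
    dG_system: float  # J mol⁻¹
    feasible: bool


def energy_budget(dG_C: float, dG_pT: float) -> EnergyBudget:
    """Combine intrinsic closing ΔG_C with the sensor penalty ΔG_pT."""
    if dG_pT < 0:
        raise ValueError("the sensor penalty dG_pT is non-negative by definition")
    total = dG_C + dG_pT
    return EnergyBudget(dG_C=dG_C, dG_pT=dG_pT, dG_system=total, feasible=total < 0)
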