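"""Cavity optics: loss rate, coupling, photon number, WGM mode solver,
effective mode volume, hotspot intensity and excess polarisability.

The chain implemented here converts the directly measurable quantities of
an optoplasmonic WGM experiment — linewidth δλ, transmission-dip depth S,
input power P — into the intracavity photon number N_in and, with the mode
volume of the plasmon-enhanced hotspot, the light intensity I at the
analyte. The mode solver finds whispering-gallery resonances of a dielectric
microsphere from the TE/TM characteristic equation (interior spherical
Bessel solution matched to the exterior evanescent solution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special

from .config import SensorConfig
from .constants import CODATA

MW_PER_CM2 = 1e10  # W m⁻² per MW cm⁻²


# --------------------------------------------------------------------------
# loss rate, coupling, photons
# --------------------------------------------------------------------------

@dataclass
class CavityState:
    """Loss/coupling rates and photon numbers of the driven cavity.

    ``N_i = 4Pλ0/(κhc)`` is the number of photons reaching the cavity per
    lifetime and ``N_in = a·N_i`` the steady-state intracavity photon
    number, with ``a = κ_in/κ`` the coupling fraction on the under-coupled
    branch (0 ≤ a ≤ 1/2).
    """

    kappa: float  # total loss rate (s⁻¹)
    kappa_in: float  # fiber–cavity coupling rate (s⁻¹)
    a: float  # coupling fraction κ_in/κ
    nu0: float  # resonance frequency (Hz)
    N_i: float
    N_in: float


def kappa_from_linewidth(dlambda: float, lambda0: float) -> float:
    """Total cavity loss rate κ = 2πc·δλ/λ0² from the linewidth (FWHM)."""
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    if dlambda < 0:
        raise ValueError("linewidth must be non-negative")
    return 2 * math.pi * CODATA.c * dlambda / lambda0**2


def linewidth_from_kappa(kappa: float, lambda0: float) -> float:
    """Inverse of :func:`kappa_from_linewidth`."""
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    return kappa * lambda0**2 / (2 * math.pi * CODATA.c)


def coupling_fraction(S: float) -> float:
    """Under-coupled coupling fraction a from the dip depth S.

    Solves a² − a + S/4 = 0 on the branch a = (1 − √(1−S))/2 ∈ [0, 1/2];
    the identity S = 4a(1−a) holds exactly.
    """
    if not 0 <= S <= 1:
        raise ValueError("coupling efficiency S must lie in [0, 1]")
    return (1.0 - math.sqrt(1.0 - S)) / 2.0


def intracavity_photons(config: SensorConfig, kappa: float, a: float) -> CavityState:
    """Photon numbers at the cavity for input power P and loss rate κ."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not 0 <= a <= 0.5:
        raise ValueError("coupling fraction must lie in [0, 0.5]")
    N_i = 4.0 * config.P * config.lambda0 / (kappa * CODATA.h * CODATA.c)
    return CavityState(
        kappa=kappa,
        kappa_in=a * kappa,
        a=a,
        nu0=CODATA.c / config.lambda0,
        N_i=N_i,
        N_in=a * N_i,
    )


def intensity_at_enzyme(state: CavityState, mode_volume: float, lambda0: float) -> float:
    """Hotspot intensity I = hν0·N_in·c/V_eff (W m⁻²).

    The photon energy is hν0 = hc/λ0. Divide by :data:`MW_PER_CM2` for the
    conventional MW cm⁻² display unit.
    """
    if mode_volume <= 0:
        raise ValueError("mode volume must be positive")
    photon_energy = CODATA.h * CODATA.c / lambda0
    return photon_energy * state.N_in * CODATA.c / mode_volume


def power_for_intensity(
    intensity: float, kappa: float, a: float, mode_volume: float
) -> float:
    """Input power P achieving a target hotspot intensity (W m⁻²).

    Inverts the chain I = 4·P·a·c/(κ·V_eff), which follows from composing
    the photon-number and intensity formulas.
    """
    if a <= 0:
        raise ValueError("coupling fraction must be positive to deliver power")
    return intensity * kappa * mode_volume / (4.0 * a * CODATA.c)


def excess_polarisability(dlambda: float, lambda0: float, V_eff: float) -> float:
    """Excess polarisability α_ex = 2·V_eff·Δλ/λ0 (volume convention, m³).

    From first-order cavity perturbation theory, Δλ/λ0 = α_ex/(2·V_eff).
    """
    if V_eff <= 0:
        raise ValueError("V_eff must be positive")
    return 2.0 * V_eff * dlambda / lambda0


# --------------------------------------------------------------------------
# microsphere mode solver
# --------------------------------------------------------------------------

@dataclass
class ModeField:
    """A whispering-gallery mode of a dielectric microsphere.

    The radial profile ``E`` (normalized to max 1) is sampled on ``r`` over
    [0, 3R]; the angular dependence of the fundamental polar mode
    (|m| = l) is the normalized spherical harmonic Y_l^l, handled in
    closed form by :func:`effective_mode_volume`. ``eps`` is the relative
    permittivity profile n².
    """

    radius: float
    n_sphere: float
    n_medium: float
    l: int
    m: int
    radial_order: int
    polarization: str
    resonance_wavelength: float
    r: np.ndarray
    E: np.ndarray
    eps: np.ndarray
    r_s: float  # hotspot position (sphere surface, equator)
    residual: float  # relative characteristic-equation residual at resonance


def _riccati_logderiv_j(l: int, z: float) -> float:
    """ψ'_l(z)/ψ_l(z) with ψ_l(z) = z·j_l(z)."""
    j = special.spherical_jn(l, z)
    jp = special.spherical_jn(l, z, derivative=True)
    return 1.0 / z + jp / j


def _riccati_logderiv_y(l: int, z: float) -> float:
    """χ'_l(z)/χ_l(z) with χ_l(z) = −z·y_l(z) (evanescent exterior)."""
    y = special.spherical_yn(l, z)
    yp = special.spherical_yn(l, z, derivative=True)
    return 1.0 / z + yp / y


def _characteristic(l: int, k: float, R: float, n1: float, n2: float, pol: str) -> float:
    """Real WGM characteristic function; roots are resonances.

    Derived from the Mie scattering coefficient denominators (b_l for TE,
    a_l for TM) with the outgoing Hankel function replaced by its dominant,
    radially decaying Neumann part — the standard high-Q approximation in
    the evanescent region below the radiation caustic.
    """
    z1, z2 = n1 * k * R, n2 * k * R
    ratio = n2 / n1 if pol == "TE" else n1 / n2
    return _riccati_logderiv_j(l, z1) - ratio * _riccati_logderiv_y(l, z2)


def _roots_for_order(
    l: int, R: float, n1: float, n2: float, pol: str, n_roots: int
) -> list[float]:
    """First ``n_roots`` resonance wavenumbers k for polar order l, ascending.

    The q-th radial order lies near z1 = n1·k·R ≈ l + α_q·(l/2)^{1/3} with
    α_q the q-th Airy zero, so scanning z1 over [l, l + 6·l^{1/3}] covers
    the low radial orders.
    """
    lo = (l + 0.05 * max(l, 1) ** (1.0 / 3.0)) / (n1 * R)
    hi = (l + 6.5 * max(l, 1) ** (1.0 / 3.0)) / (n1 * R)
    ks = np.linspace(lo, hi, 400)
    vals = np.array([_characteristic(l, k, R, n1, n2, pol) for k in ks])
    roots: list[float] = []
    for i in range(len(ks) - 1):
        if not (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])):
            continue
        if vals[i] == 0.0:
            roots.append(float(ks[i]))
            continue
        if vals[i] * vals[i + 1] < 0:
            try:
                k_root = optimize.brentq(
                    lambda k: _characteristic(l, k, R, n1, n2, pol),
                    ks[i],
                    ks[i + 1],
                    xtol=1e-18,
                    rtol=8.9e-16,
                )
            except ValueError:
                continue
            # discard poles (zeros of the Bessel denominators look like
            # sign changes too, but the function value stays large there)
            if _relative_residual(l, k_root, R, n1, n2, pol) < 1e-8:
                roots.append(float(k_root))
        if len(roots) >= n_roots:
            break
    return roots


def _relative_residual(l: int, k: float, R: float, n1: float, n2: float, pol: str) -> float:
    z1, z2 = n1 * k * R, n2 * k * R
    ratio = n2 / n1 if pol == "TE" else n1 / n2
    t1 = _riccati_logderiv_j(l, z1)
    t2 = ratio * _riccati_logderiv_y(l, z2)
    scale = max(abs(t1), abs(t2), 1e-300)
    return abs(t1 - t2) / scale


def free_spectral_range(lambda0: float, R: float, n_sphere: float) -> float:
    """Approximate FSR λ²/(2πRn) of a microsphere WGM ladder."""
    return lambda0**2 / (2 * math.pi * R * n_sphere)


def solve_microsphere_mode(
    R: float,
    n_sphere: float,
    n_medium: float,
    lambda_target: float,
    polarization: str = "TE",
    radial_order: int = 1,
    n_samples: int = 3000,
) -> ModeField:
    """Find the WGM of given radial order with resonance nearest λ_target.

    The polar order l is scanned over the geometric-optics window
    n_medium·kR < l < n_sphere·kR (with margin); for each l the
    characteristic equation is root-found in k and the ``radial_order``-th
    root kept; the (l, λ) pair closest to λ_target wins. The radial field
    profile — interior j_l(n1kr), exterior evanescent y_l(n2kr), matched at
    the surface — is sampled on [0, 3R].

    Raises
    ------
    RuntimeError
        If no resonance lies within one free spectral range of λ_target.
    """
    if not (n_sphere > n_medium >= 1):
        raise ValueError("need n_sphere > n_medium >= 1")
    if R < 10 * lambda_target:
        raise ValueError("solver assumes R much larger than the wavelength")
    if polarization not in ("TE", "TM"):
        raise ValueError("polarization must be 'TE' or 'TM'")

    k_target = 2 * math.pi / lambda_target
    l_hi = int(math.ceil(n_sphere * k_target * R)) + 5
    l_lo = max(1, int(math.floor(n_medium * k_target * R)) - 5)

    best: Optional[tuple[float, int, float]] = None  # (|Δλ|, l, k)
    for l in range(l_lo, l_hi + 1):
        roots = _roots_for_order(l, R, n_sphere, n_medium, polarization, radial_order)
        if len(roots) < radial_order:
            continue
        k_res = roots[radial_order - 1]
        lam = 2 * math.pi / k_res
        d = abs(lam - lambda_target)
        if best is None or d < best[0]:
            best = (d, l, k_res)

    fsr = free_spectral_range(lambda_target, R, n_sphere)
    if best is None or best[0] > fsr:
        raise RuntimeError(
            f"no {polarization} mode of radial order {radial_order} within one "
            f"FSR ({fsr * 1e9:.2f} nm) of {lambda_target * 1e9:.2f} nm"
        )
    _, l, k_res = best
    lam_res = 2 * math.pi / k_res

    r = np.linspace(0.0, 3 * R, n_samples)
    inside = r <= R
    E = np.empty_like(r)
    E[inside] = special.spherical_jn(l, n_sphere * k_res * r[inside])
    jR = special.spherical_jn(l, n_sphere * k_res * R)
    yR = special.spherical_yn(l, n_medium * k_res * R)
    # tangential-E continuity (TE); for TM the dominant radial component
    # jumps by the permittivity ratio at the boundary
    match = jR / yR
    if polarization == "TM":
        match *= (n_sphere / n_medium) ** 2
    E[~inside] = match * special.spherical_yn(l, n_medium * k_res * r[~inside])
    scale = np.max(np.abs(E))
    E /= scale
    eps = np.where(inside, n_sphere**2, n_medium**2)

    return ModeField(
        radius=R,
        n_sphere=n_sphere,
        n_medium=n_medium,
        l=l,
        m=l,
        radial_order=radial_order,
        polarization=polarization,
        resonance_wavelength=lam_res,
        r=r,
        E=E,
        eps=eps,
        r_s=R,
        residual=_relative_residual(l, k_res, R, n_sphere, n_medium, polarization),
    )


# --------------------------------------------------------------------------
# mode volume, hotspot
# --------------------------------------------------------------------------

@dataclass
class HotspotModel:
    """Plasmon-enhanced hotspot summary: mode volume, intensity, polarisability."""

    V_eff: float  # m³
    I: float  # W m⁻²
    alpha_ex: Optional[float] = None  # m³

    @property
    def I_mw_cm2(self) -> float:
        return self.I / MW_PER_CM2


def effective_volume(
    energy_integral: float, eps_hotspot: float, E2_hotspot: float, Lambda_: float
) -> float:
    """Normalization identity V_eff = ∫ε|E|²dV / (Λ·ε(r_s)|E(r_s)|²).

    With a uniform unit field over a region and the hotspot inside it,
    V_eff at Λ=1 equals the region's volume.
    """
    if Lambda_ < 1:
        raise ValueError("enhancement factor must be >= 1")
    denom = Lambda_ * eps_hotspot * E2_hotspot
    if denom <= 0:
        raise ValueError("zero field or permittivity at the hotspot")
    return energy_integral / denom


def _Yll_peak_sq(l: int) -> float:
    """|Y_l^l(θ=π/2)|², the equatorial peak of the fundamental polar mode."""
    # |Y_l^l|² = (2l+1)/(4π) · (2l)!/(4^l (l!)²) · sin^{2l}θ
    log_c = special.gammaln(2 * l + 1) - 2 * special.gammaln(l + 1) - 2 * l * math.log(2.0)
    return (2 * l + 1) / (4 * math.pi) * math.exp(log_c)


def effective_mode_volume(
    mode: ModeField, Lambda_: float, r_s: Optional[float] = None
) -> float:
    """Plasmon-enhanced effective mode volume of a microsphere WGM (m³).

    The numerator ∫ε(r)|E|²d³r is a radial quadrature of ε(r)|E(r)|²r²
    times the unit angular integral of the normalized |Y_l^l|²; the
    denominator evaluates Λ·ε·|E|² at the hotspot r_s on the equator,
    where |Y_l^l|² peaks. Scales exactly as 1/Λ.
    """
    r_s = mode.r_s if r_s is None else r_s
    E_s = float(np.interp(r_s, mode.r, mode.E))
    if E_s == 0:
        raise ValueError("zero field at the hotspot position")
    eps_s = mode.n_sphere**2 if r_s <= mode.radius else mode.n_medium**2
    peak = _Yll_peak_sq(mode.l)
    radial = float(np.trapezoid(mode.eps * mode.E**2 * mode.r**2, mode.r))
    return effective_volume(radial, eps_s, E_s**2 * peak, Lambda_)
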