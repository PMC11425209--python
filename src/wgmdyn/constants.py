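"""Physical constants (CODATA, via :mod:`scipy.constants`).

These are fixed values, never user-configurable: the work and free-energy
chain (photon energy, intracavity photon number, β = 1/k_BT) must use the
same constants everywhere or the round-trip identities between the compact
work equation and its step-by-step derivation break down.
"""

from dataclasses import dataclass

import scipy.constants as _sc


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used throughout the work/energy chain.

    Attributes
    ----------
    N_A : Avogadro constant (mol⁻¹)
    h : Planck constant (J s)
    c : speed of light in vacuum (m s⁻¹)
    k_B : Boltzmann constant (J K⁻¹)
    R : molar gas constant N_A·k_B (J mol⁻¹ K⁻¹)
    """

    N_A: float = _sc.N_A
    h: float = _sc.h
    c: float = _sc.c
    k_B: float = _sc.k

    @property
    def R(self) -> float:
        return self.N_A * self.k_B


#: The single shared instance; import this rather than instantiating.
CODATA = PhysicalConstants()
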