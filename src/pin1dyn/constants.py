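"""Physical-constant bundles for relaxation and PRE forward models.

All constants are SI (CODATA 2018). Rates are handled in rad/s throughout the
package, distances in Å at API boundaries (converted to metres internally).
"""
from __future__ import annotations

from dataclasses import dataclass, field
import math

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative; magnitudes used in C_N/D_IN)
GAMMA_N = -2.7126189e7
#: reduced Planck constant, J s
HBAR = 1.054571817e-34
#: mu_0 / 4 pi, T m A^-1 (equivalently T^2 m^3 J^-1)
MU0_OVER_4PI = 1.0e-7
#: Bohr magneton, J T^-1
MU_B = 9.2740100783e-24
#: free-electron g factor (magnitude)
G_ELECTRON = 2.00231930436


@dataclass(frozen=True)
class NMRConstants:
    """Constant bundle for the 15N R2-R1/2 -> J_eff(0) -> tau_c conversion.

    The combination R2-R1/2 of backbone amide 15N rates is proportional to
    J_eff(0), with the proportionality set by the 15N CSA term C_N and the
    1H-15N dipolar term D_IN:

        R2 - R1/2 = (2 C_N / 3) (1 + 3 D_IN / C_N) J_eff(0)
        C_N  = (omega_N * delta_sigma_N)^2 / 3
        D_IN = ((mu0/4pi) hbar gamma_H gamma_N / r_NH^3)^2
        J_eff(0) = 2 tau_c / 5

    Parameters
    ----------
    field_mhz : spectrometer 1H frequency in MHz (default 700.13).
    delta_sigma_n : 15N CSA, dimensionless (default -170 ppm).
    r_nh : N-H bond length in metres (default 1.02 Å).
    """

    field_mhz: float = 700.13
    delta_sigma_n: float = -170e-6
    r_nh: float = 1.02e-10
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N
    hbar: float = HBAR
    mu0_over_4pi: float = MU0_OVER_4PI

    def __post_init__(self):
        if self.field_mhz <= 0 or self.r_nh <= 0:
            raise ValueError("field strength and r_NH must be positive")

    @property
    def b0(self) -> float:
        """Static field in tesla, from the configured 1H frequency."""
        return 2.0 * math.pi * self.field_mhz * 1e6 / self.gamma_h

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency magnitude, rad/s."""
        return abs(self.gamma_n) * self.b0

    @property
    def c_n(self) -> float:
        """CSA interaction constant C_N, rad^2/s^2."""
        return (self.omega_n * abs(self.delta_sigma_n)) ** 2 / 3.0

    @property
    def d_in(self) -> float:
        """Dipolar interaction constant D_IN, rad^2/s^2."""
        d = (
            self.mu0_over_4pi
            * self.hbar
            * self.gamma_h
            * abs(self.gamma_n)
            / self.r_nh**3
        )
        return d * d

    @property
    def rate_per_jeff0(self) -> float:
        """Proportionality between R2-R1/2 (rad/s) and J_eff(0) (s/rad)."""
        return (2.0 * self.c_n / 3.0) * (1.0 + 3.0 * self.d_in / self.c_n)


@dataclass(frozen=True)
class SBConstants:
    """Constant bundle for the Solomon-Bloembergen transverse PRE.

    Defaults describe a nitroxide spin label (S = 1/2) observed via amide
    protons at a 700.13 MHz spectrometer. ``prefactor`` is the unit-system
    factor multiplying the dipolar term; the SI default is (mu0/4pi)^2.
    """

    s_spin: float = 0.5
    g: float = G_ELECTRON
    mu_b: float = MU_B
    gamma_i: float = GAMMA_H
    field_mhz: float = 700.13
    prefactor: float = MU0_OVER_4PI**2

    def __post_init__(self):
        for name in ("s_spin", "g", "mu_b", "gamma_i", "field_mhz", "prefactor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SBConstants.{name} must be positive")

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency, rad/s."""
        return 2.0 * math.pi * self.field_mhz * 1e6
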