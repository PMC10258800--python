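"""Physical constants, unit conversions and NMR parameters.

Single source of truth for every module: lengths are nm, times ps,
diffusion coefficients cross the API boundary in SI (m^2 s^-1), dipolar
correlation functions are in nm^-6 and spectral densities in nm^-6 ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAMMA_H = 2.675222e8
"""1H gyromagnetic ratio, rad s^-1 T^-1."""

GAMMA_F = 2.518148e8
"""19F gyromagnetic ratio, rad s^-1 T^-1."""

HBAR = 1.054572e-34
"""Reduced Planck constant, J s."""

MU0_OVER_4PI = 1e-7
"""mu_0 / 4 pi, T^2 J^-1 m^3."""

M2S_TO_NM2PS = 1e6
"""1 m^2 s^-1 = 1e6 nm^2 ps^-1."""

NM2PS_TO_M2S = 1e-6

NM6PS_TO_SI = 1e42
"""1 nm^-6 ps = 1e42 m^-6 s (1 nm^-6 = 1e54 m^-6, 1 ps = 1e-12 s)."""

RAD_S_TO_RAD_PS = 1e-12

DEFAULT_B0_TESLA = 11.744
"""Default magnetic field (500 MHz 1H). The source experiments do not state
the spectrometer field; reports must echo the field actually used."""


def d_si_to_nm2_per_ps(d_m2_s: float) -> float:
    """Convert a diffusion coefficient from m^2 s^-1 to nm^2 ps^-1."""
    return d_m2_s * M2S_TO_NM2PS


def d_nm2_per_ps_to_si(d_nm2_ps: float) -> float:
    return d_nm2_ps * NM2PS_TO_M2S


@dataclass(frozen=True)
class NMRParameters:
    """Static magnetic field and gyromagnetic ratios for the H-F spin pair.

    Larmor frequencies are derived: omega = gamma * B0 (rad s^-1).
    """

    b0: float = DEFAULT_B0_TESLA
    gamma_h: float = GAMMA_H
    gamma_f: float = GAMMA_F

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError(f"B0 must be positive, got {self.b0}")
        if not (self.omega_h > self.omega_f > 0):
            raise ValueError("expected omega_H > omega_F > 0")

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency, rad s^-1."""
        return self.gamma_h * self.b0

    @property
    def omega_f(self) -> float:
        """19F Larmor frequency, rad s^-1."""
        return self.gamma_f * self.b0

    @property
    def omega_sum(self) -> float:
        """omega_H + omega_F, rad s^-1 (double-quantum combination)."""
        return self.omega_h + self.omega_f

    @property
    def omega_diff(self) -> float:
        """omega_H - omega_F, rad s^-1 (zero-quantum combination)."""
        return self.omega_h - self.omega_f


SIGMA_PREFACTOR = 0.1 * MU0_OVER_4PI**2 * HBAR**2 * GAMMA_H**2 * GAMMA_F**2
"""(1/10) (mu0/4pi)^2 hbar^2 gamma_H^2 gamma_F^2, m^6 s^-2.

Multiplied by a spectral density in SI (m^-6 s) this yields a rate in s^-1.
The 1/10 goes with the one-sided cosine transform and the P2/r^3 r^3 lattice
function used throughout; the identical constant is applied on the simulated
and the analytic side, so cross-comparisons are convention-free.
"""


def sigma_from_spectral_densities(j_sum_nm6ps: float, j_diff_nm6ps: float) -> float:
    """Cross-relaxation rate Sigma_HF = prefactor * (6 J(w_H+w_F) - J(w_H-w_F)).

    Parameters
    ----------
    j_sum_nm6ps, j_diff_nm6ps:
        Spectral densities at the double- and zero-quantum combination
        frequencies, in nm^-6 ps.

    Returns
    -------
    Rate in s^-1; may be negative (slow-motion regime).
    """
    return SIGMA_PREFACTOR * (6.0 * j_sum_nm6ps - j_diff_nm6ps) * NM6PS_TO_SI
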