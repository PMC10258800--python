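"""Force-free hard-sphere model of translational cross-relaxation.

Analytic reference for the trajectory pipeline: spins of density N_F
diffuse freely (mutual coefficient D) outside a reflecting sphere of
radius b (the distance of closest approach) centred on the reference spin.
The reduced spectral density has the exact closed form

    j(z) = (1 + 5z/8 + z^2/8) /
           (1 + z + z^2/2 + z^3/6 + 4z^4/81 + z^5/81 + z^6/648),
    z = sqrt(2 w tau_b),  tau_b = b^2 / D,

and the absolute scale is pinned numerically by quadrature of the
reflecting-boundary diffusion propagator under the same G(t) normalisation
as the trajectory pipeline (sum over spins of P2(cos theta)/r0^3 r^3 with
uniform density N_F), rather than by transcribing a literature prefactor:
the propagator expansion in spherical Bessel modes gives

    G(t) = (8 N_F / b^3) Int_0^inf x^2 e^(-D t x^2 / b^2) A(x)^2 / W(x) dx
    A(x) = [y2'(x) j1(x) - j2'(x) y1(x)] / x,   W(x) = j2'(x)^2 + y2'(x)^2

with j_l, y_l spherical Bessel functions (the radial overlap integral of
u2(kr)/r has the closed form above). J(0) = (8 N_F / (b D)) * I0 with the
dimensionless constant I0 = Int A^2/W dx ~= 0.2327 (tau_eff = (4/9) tau_b).
The quadrature path doubles as an independent check of the closed form.

An ``origin_cutoff`` restricts the *origin* radial integral to b..R,
matching the pipeline's convention of only summing spins within the
cutoff at the origin frame; the lagged position remains unrestricted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import spherical_jn, spherical_yn

from .constants import (
    NMRParameters,
    RAD_S_TO_RAD_PS,
    d_si_to_nm2_per_ps,
    sigma_from_spectral_densities,
)

_QUAD_BREAKS = (1e-8, 5.0, 20.0, 100.0, 400.0)


@dataclass(frozen=True)
class HardSphereParams:
    """b (nm), mutual D (m^2 s^-1), fluorine density N_F (nm^-3), NMR field."""

    b: float
    d_mutual: float
    n_f: float
    nmr: NMRParameters = field(default_factory=NMRParameters)

    def __post_init__(self) -> None:
        if self.b <= 0 or self.d_mutual <= 0 or self.n_f <= 0:
            raise ValueError("b, d_mutual and n_f must all be positive")

    @property
    def tau_b(self) -> float:
        """Translational correlation time b^2/D, ps."""
        return self.b**2 / d_si_to_nm2_per_ps(self.d_mutual)


def reduced_spectral_density(z):
    """Exact reduced spectral density j(z) of the force-free model; j(0)=1."""
    z = np.asarray(z, dtype=np.float64)
    num = 1 + 5 * z / 8 + z**2 / 8
    den = 1 + z + z**2 / 2 + z**3 / 6 + 4 * z**4 / 81 + z**5 / 81 + z**6 / 648
    return num / den


def _overlap(x):
    return (
        spherical_yn(2, x, derivative=True) * spherical_jn(1, x)
        - spherical_jn(2, x, derivative=True) * spherical_yn(1, x)
    ) / x


def _overlap_cut(x, ratio):
    """Origin integral restricted to b..R, R/b = ratio (closed form)."""
    xr = x * ratio
    return spherical_yn(2, x, derivative=True) * (
        spherical_jn(1, x) / x - spherical_jn(1, xr) / xr
    ) - spherical_jn(2, x, derivative=True) * (
        spherical_yn(1, x) / x - spherical_yn(1, xr) / xr
    )


def _mode_weight(x):
    return (
        spherical_jn(2, x, derivative=True) ** 2
        + spherical_yn(2, x, derivative=True) ** 2
    )


def _piecewise_quad(f):
    return sum(
        quad(f, lo, hi, limit=400)[0] for lo, hi in zip(_QUAD_BREAKS, _QUAD_BREAKS[1:])
    )


@lru_cache(maxsize=1)
def _i0_constant() -> float:
    """I0 = Int_0^inf A(x)^2 / W(x) dx (dimensionless, ~0.23271)."""
    return _piecewise_quad(lambda x: _overlap(x) ** 2 / _mode_weight(x))


@lru_cache(maxsize=256)
def _j_reduced_cut(wt: float, ratio: float) -> float:
    """Int x^4 A_R A / ((x^4 + (w tau)^2) W) dx for the cutoff-matched scale."""
    return _piecewise_quad(
        lambda x: x**4
        * _overlap_cut(x, ratio)
        * _overlap(x)
        / ((x**4 + wt * wt) * _mode_weight(x))
    )


def hard_sphere_correlation(
    p: HardSphereParams, t_ps, origin_cutoff: float | None = None
) -> np.ndarray:
    """G(t) of the force-free model by propagator quadrature, nm^-6."""
    d_nm = d_si_to_nm2_per_ps(p.d_mutual)
    ratio = None if origin_cutoff is None else origin_cutoff / p.b
    out = []
    for t in np.atleast_1d(np.asarray(t_ps, dtype=np.float64)):
        a = d_nm * t / p.b**2
        if ratio is None:
            f = lambda x: x**2 * np.exp(-a * x**2) * _overlap(x) ** 2 / _mode_weight(x)
        else:
            f = (
                lambda x: x**2
                * np.exp(-a * x**2)
                * _overlap_cut(x, ratio)
                * _overlap(x)
                / _mode_weight(x)
            )
        out.append(8 * p.n_f / p.b**3 * _piecewise_quad(f))
    return np.array(out)


def ayant_spectral_density(
    p: HardSphereParams, omega, origin_cutoff: float | None = None
):
    """J(w), nm^-6 ps, for w in rad s^-1 (scalar or array, w >= 0).

    Default: exact closed form J(0) j(z) with the numerically pinned scale
    J(0) = (8 N_F / (b D)) I0. With ``origin_cutoff`` (nm) the full
    quadrature is used so the origin-restricted normalisation matches the
    trajectory pipeline's cutoff convention.
    """
    om = np.atleast_1d(np.asarray(omega, dtype=np.float64))
    if np.any(om < 0):
        raise ValueError("omega must be >= 0")
    d_nm = d_si_to_nm2_per_ps(p.d_mutual)
    scale = 8 * p.n_f / (p.b * d_nm)
    wt = om * RAD_S_TO_RAD_PS * p.tau_b
    if origin_cutoff is None:
        j = scale * _i0_constant() * reduced_spectral_density(np.sqrt(2 * wt))
    else:
        if origin_cutoff <= p.b:
            raise ValueError("origin_cutoff must exceed b")
        ratio = origin_cutoff / p.b
        j = scale * np.array([_j_reduced_cut(float(w), ratio) for w in wt])
    return j if np.ndim(omega) else float(j[0])


def ayant_sigma(p: HardSphereParams, origin_cutoff: float | None = None) -> float:
    """Sigma_HF of the hard-sphere model, s^-1 (same prefactor as the pipeline)."""
    j_sum = ayant_spectral_density(p, p.nmr.omega_sum, origin_cutoff)
    j_diff = ayant_spectral_density(p, p.nmr.omega_diff, origin_cutoff)
    return sigma_from_spectral_densities(j_sum, j_diff)


def sigma_scan(p: HardSphereParams, variable: str, grid) -> pd.DataFrame:
    """Sigma_HF along a parameter grid, with sign-crossover refinement.

    ``variable`` is one of ``B0``, ``D_mutual``, ``b``. The returned frame
    carries ``attrs['crossovers']`` with brentq-refined sign-change
    locations (empty if the scan does not change sign).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("scan grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("scan grid must be sorted increasing")

    def sig_at(v: float) -> float:
        if variable == "B0":
            q = HardSphereParams(p.b, p.d_mutual, p.n_f, NMRParameters(b0=v))
        elif variable == "D_mutual":
            q = HardSphereParams(p.b, v, p.n_f, p.nmr)
        elif variable == "b":
            q = HardSphereParams(v, p.d_mutual, p.n_f, p.nmr)
        else:
            raise ValueError(f"unknown scan variable {variable!r}")
        return ayant_sigma(q)

    sigmas = np.array([sig_at(v) for v in grid])
    crossovers = []
    for i in range(len(grid) - 1):
        if sigmas[i] == 0.0:
            crossovers.append(float(grid[i]))
        elif sigmas[i] * sigmas[i + 1] < 0:
            crossovers.append(float(brentq(sig_at, grid[i], grid[i + 1], xtol=1e-12)))
    df = pd.DataFrame({variable: grid, "sigma_hf": sigmas})
    df.attrs["crossovers"] = crossovers
    return df
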