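"""Heteronuclear cross-relaxation rates Sigma_HF from spectral densities.

Sigma_HF = (1/10) (mu0/4pi)^2 hbar^2 gamma_H^2 gamma_F^2
           [6 J(w_H + w_F) - J(w_H - w_F)]

with J the one-sided cosine transform of the dipolar correlation function.
The sign may be negative: slow solvent dynamics push weight from the
double-quantum term 6J(w_H+w_F) into J(w_H-w_F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import NMRParameters, RAD_S_TO_RAD_PS, sigma_from_spectral_densities
from .correlation import CorrelationFunction
from .expfit import ExpFitResult, fit_multiexponential, spectral_density_from_fit


@dataclass
class CrossRelaxationResult:
    """Sigma_HF (s^-1) with the spectral densities that produced it."""

    sigma_hf: float
    j_sum: float  # nm^-6 ps at w_H + w_F
    j_diff: float  # nm^-6 ps at w_H - w_F
    b0: float  # T, field actually used (reports must echo it)
    reference_hydrogen: str = ""
    shell_contributions: dict | None = None  # shell label -> rate
    uncertainty: float | None = None  # mean abs deviation over replicates
    n_replicates: int = 1

    def __post_init__(self) -> None:
        expected = sigma_from_spectral_densities(self.j_sum, self.j_diff)
        if self.n_replicates == 1 and abs(self.sigma_hf - expected) > 1e-12 * max(
            abs(expected), 1e-30
        ):
            raise ValueError("sigma_hf inconsistent with its spectral densities")


def _check_units(fit: ExpFitResult) -> None:
    if fit.time_unit != "ps" or fit.value_unit != "nm^-6":
        raise ValueError(
            f"fit carries units ({fit.value_unit}, {fit.time_unit}); expected "
            "nm^-6 vs ps -- silent unit mismatches dominate this computation"
        )


def sigma_hf(
    fit: ExpFitResult,
    nmr: NMRParameters | None = None,
    reference_hydrogen: str = "",
) -> CrossRelaxationResult:
    """Sigma_HF from a fitted correlation function."""
    nmr = nmr or NMRParameters()
    _check_units(fit)
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to integrate it")
    w_sum = nmr.omega_sum * RAD_S_TO_RAD_PS
    w_diff = nmr.omega_diff * RAD_S_TO_RAD_PS
    j_sum = spectral_density_from_fit(fit, w_sum)
    j_diff = spectral_density_from_fit(fit, w_diff)
    return CrossRelaxationResult(
        sigma_hf=sigma_from_spectral_densities(j_sum, j_diff),
        j_sum=j_sum,
        j_diff=j_diff,
        b0=nmr.b0,
        reference_hydrogen=reference_hydrogen,
    )


def sigma_shell_decomposition(
    shell_corrs: list[CorrelationFunction],
    nmr: NMRParameters | None = None,
    max_terms: int = 5,
) -> CrossRelaxationResult:
    """Per-shell Sigma_HF from shell-resolved correlation functions.

    Each shell is fitted separately; the total is the sum of shell rates
    (the shell functions partition the all-solvent G(t) exactly). Shells
    with zero signal contribute zero. A consistency warning is recorded if
    shell fit orders differ wildly.
    """
    nmr = nmr or NMRParameters()
    if not shell_corrs:
        raise ValueError("need at least one shell correlation")
    contributions: dict[str, float] = {}
    js, jd = 0.0, 0.0
    orders = []
    ref = shell_corrs[0].reference_hydrogen
    for corr in shell_corrs:
        if corr.reference_hydrogen != ref:
            raise ValueError("shell correlations mix reference hydrogens")
        if np.abs(corr.values).max() == 0.0:
            contributions[corr.shell_label] = 0.0
            continue
        fit = fit_multiexponential(corr, max_terms=max_terms)
        res = sigma_hf(fit, nmr, reference_hydrogen=ref)
        contributions[corr.shell_label] = res.sigma_hf
        js += res.j_sum
        jd += res.j_diff
        orders.append(fit.n_terms)
    if orders and max(orders) - min(orders) > 3:
        warnings.warn(
            f"shell fits used widely different orders {sorted(set(orders))}",
            stacklevel=2,
        )
    total = sigma_from_spectral_densities(js, jd)
    return CrossRelaxationResult(
        sigma_hf=total,
        j_sum=js,
        j_diff=jd,
        b0=nmr.b0,
        reference_hydrogen=ref,
        shell_contributions=contributions,
    )


def average_over_replicates(
    results: list[CrossRelaxationResult],
) -> CrossRelaxationResult:
    """Replicate mean with mean-absolute-deviation uncertainty.

    The uncertainty convention is the mean deviation from the mean, the
    same convention as the replicate-averaged tables this mirrors.
    """
    if len(results) < 2:
        raise ValueError("need at least two replicate results")
    ref = results[0].reference_hydrogen
    b0 = results[0].b0
    for r in results[1:]:
        if r.reference_hydrogen != ref:
            raise ValueError("cannot average results for different hydrogens")
        if r.b0 != b0:
            raise ValueError("cannot average results at different fields")
    sig = np.array([r.sigma_hf for r in results])
    mean = float(sig.mean())
    return CrossRelaxationResult(
        sigma_hf=mean,
        j_sum=float(np.mean([r.j_sum for r in results])),
        j_diff=float(np.mean([r.j_diff for r in results])),
        b0=b0,
        reference_hydrogen=ref,
        uncertainty=float(np.abs(sig - mean).mean()),
        n_replicates=len(results),
    )
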