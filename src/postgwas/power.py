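"""Case-control association power under the liability-threshold model.

A disease with prevalence ``K`` is modelled as an unobserved standard
normal liability exceeding the threshold ``T = Phi^-1(1 - K)``.  A SNP
explaining a share ``h2_l`` of liability variance has, in a case-control
sample with case fraction ``P``, an observed-scale (0/1 disease trait)
variance share of

    h2_obs = h2_l * z^2 * P (1 - P) / (K (1 - K))^2

where ``z = phi(T)`` is the standard-normal density at the threshold (the
ascertainment-corrected liability-to-observed transformation of Lee/Yang).
The non-centrality parameter of the 1-df association chi-square is then
``NCP = N * h2_obs``, linear in the total sample size.  Power at level
``alpha`` is the noncentral chi-square tail beyond the central critical
value.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .types import StudyDesign

__all__ = [
    "StudyDesign",
    "PowerResult",
    "truncation_z",
    "liab_to_observed_h2",
    "ncp",
    "power_from_ncp",
    "ncp_fold",
]


@dataclass
class PowerResult:
    """NCP (and, when an alpha was given, detection probability)."""

    ncp: float
    power_at_alpha: float | None = None


def truncation_z(K: float) -> float:
    """Standard-normal density at the upper-K liability threshold."""
    if not (0.0 < K < 1.0):
        raise ValidationError(f"prevalence must be in (0, 1): {K}")
    return float(stats.norm.pdf(stats.norm.ppf(1.0 - K)))


def liab_to_observed_h2(h2_liab: float, K: float, case_fraction_P: float) -> float:
    """Ascertainment-corrected liability-to-observed-scale h2 conversion."""
    if not (0.0 <= h2_liab < 1.0):
        raise ValidationError(f"liability h2 must be in [0, 1): {h2_liab}")
    if not (0.0 < case_fraction_P < 1.0):
        raise ValidationError(f"case fraction must be in (0, 1): {case_fraction_P}")
    z = truncation_z(K)
    P = case_fraction_P
    return h2_liab * z * z * P * (1.0 - P) / (K * (1.0 - K)) ** 2


def ncp(design: StudyDesign, alpha: float | None = None) -> PowerResult:
    """Expected non-centrality parameter for the design's SNP.

    ``NCP = N * h2_obs``; when ``alpha`` is given, power is attached.
    """
    value = design.n_total * liab_to_observed_h2(
        design.snp_h2_liab, design.prevalence_K, design.case_fraction
    )
    power = power_from_ncp(value, alpha) if alpha is not None else None
    return PowerResult(ncp=value, power_at_alpha=power)


def power_from_ncp(ncp_value: float, alpha: float) -> float:
    """Detection probability of a 1-df chi-square test with the given NCP."""
    if ncp_value < 0.0:
        raise ValidationError(f"NCP must be non-negative: {ncp_value}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1): {alpha}")
    crit = stats.chi2.isf(alpha, df=1)
    if ncp_value == 0.0:
        return alpha
    return float(stats.ncx2.sf(crit, df=1, nc=ncp_value))


def ncp_fold(design_a: StudyDesign, design_b: StudyDesign) -> float:
    """Ratio NCP(a) / NCP(b); reporting convention is one decimal place."""
    denom = ncp(design_b).ncp
    if denom <= 0.0:
        raise ValidationError("denominator design has zero NCP")
    return ncp(design_a).ncp / denom
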