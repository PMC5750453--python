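"""Per-SNP variance explained on the liability scale.

For a biallelic SNP with effect-allele frequency ``p`` and allelic odds
ratio ``OR``, the contribution to the variance of the (logistic-scale)
disease liability is

    var(g) = 2 p (1 - p) (ln OR)^2

and the SNP heritability is the share of the total logistic liability
variance,

    h2 = var(g) / (var(g) + pi^2 / 3),

pi^2/3 being the variance of the standard logistic residual.  Both are
invariant under the allele flip (p -> 1-p, OR -> 1/OR), so a minor-allele
frequency may be supplied in place of the effect-allele frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import RiskVariant

logger = logging.getLogger(__name__)

#: Variance of the standard logistic distribution.
LOGISTIC_VARIANCE = math.pi**2 / 3


@dataclass
class LiabilityResult:
    """Liability-variance accounting for one variant."""

    rsid: str
    var_g: float
    h2: float  # proportion in [0, 1)

    @property
    def h2_pct(self) -> float:
        return 100.0 * self.h2


def variance_explained(eaf: float, or_: float) -> float:
    """Liability-variance contribution 2 p (1-p) (ln OR)^2."""
    if not (0.0 < eaf < 1.0):
        raise ValidationError(f"effect-allele frequency must be in (0, 1): {eaf}")
    if not or_ > 0.0:
        raise ValidationError(f"odds ratio must be positive: {or_}")
    return 2.0 * eaf * (1.0 - eaf) * math.log(or_) ** 2


def snp_h2(var_g: float) -> float:
    """Proportion of logistic liability variance: var_g / (var_g + pi^2/3)."""
    if var_g < 0.0:
        raise ValidationError(f"var_g must be non-negative: {var_g}")
    return var_g / (var_g + LOGISTIC_VARIANCE)


def summarize_h2(
    variants: list[RiskVariant],
) -> tuple[list[LiabilityResult], float, float]:
    """Per-variant liability h2 plus the total and median, in percent.

    Returns ``(results, total_pct, median_pct)`` with results in input
    order.  Values are raw (unrounded) percentages; writers round to two
    decimals for display.
    """
    if not variants:
        raise ValidationError("summarize_h2 requires a non-empty variant list")
    results = []
    for v in variants:
        if v.eaf is None:
            raise ValidationError(f"{v.rsid}: an allele frequency is required for var(g)")
        vg = variance_explained(v.eaf, v.or_)
        results.append(LiabilityResult(rsid=v.rsid, var_g=vg, h2=snp_h2(vg)))
    pct = np.array([r.h2_pct for r in results])
    return results, float(pct.sum()), float(np.median(pct))


def remaining_h2(snp_based_h2_pct: float, explained_pct: float) -> float:
    """SNP-based heritability not yet explained by known variants (percent).

    The difference, floored at zero: the genome-wide SNP-based estimate and
    the sum over known variants come from different procedures and small
    samples can invert their order.
    """
    if snp_based_h2_pct < 0.0 or explained_pct < 0.0:
        raise ValidationError("heritability percentages must be non-negative")
    diff = snp_based_h2_pct - explained_pct
    if diff < 0.0:
        logger.warning(
            "explained heritability (%.3g%%) exceeds the SNP-based total (%.3g%%); flooring at 0",
            explained_pct,
            snp_based_h2_pct,
        )
        return 0.0
    return diff
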