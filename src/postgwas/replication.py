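"""Bonferroni-corrected, direction-aware replication assessment.

A reported variant replicates when its association in an independent
summary-statistics table is (a) significant after dividing alpha by the
number of variants assessed and (b) directionally consistent, i.e. the
same allele predisposes to disease after the two records are harmonized
to a common effect-allele orientation.  Test statistics are deflated by a
genomic-inflation (LD-score) intercept before the threshold is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from scipy import stats

from . import ld
from .errors import HarmonizationError, ValidationError
from .ld import HaplotypePanel
from .types import RiskVariant

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ReplicationVerdict:
    rsid: str
    proxy_used: str | None
    p_adjusted: float | None
    direction_consistent: bool
    significant: bool
    testable: bool = True
    note: str = ""


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1): {alpha}")
    if m < 1:
        raise ValidationError(f"test count must be at least 1: {m}")
    return alpha / m


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0.0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def intercept_adjust(chi2: float, intercept: float) -> tuple[float, float]:
    """Deflate a 1-df chi-square by an inflation intercept.

    Returns ``(chi2 / intercept, upper-tail P of the adjusted statistic)``.
    Intercepts below 1 are accepted with a warning (they inflate the
    statistic), non-positive intercepts are invalid.
    """
    if chi2 < 0.0:
        raise ValidationError(f"chi-square must be non-negative: {chi2}")
    if intercept <= 0.0:
        raise ValidationError(f"intercept must be positive: {intercept}")
    if intercept < 1.0:
        logger.warning("inflation intercept %.4g < 1 inflates the statistic", intercept)
    adj = chi2 / intercept
    return adj, float(stats.chi2.sf(adj, df=1))


def adjust_p(p: float, intercept: float) -> float:
    """Convert a P-value to chi-square(1), deflate, and re-evaluate the tail."""
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"P must be in (0, 1]: {p}")
    chi2 = float(stats.chi2.isf(p, df=1))
    return intercept_adjust(chi2, intercept)[1]


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return None  # indels / non-ACGT codes have no strand complement


def is_palindromic(effect_allele: str, other_allele: str | None) -> bool:
    """A/T or C/G pairs read identically on both strands."""
    if other_allele is None:
        return False
    return _complement(effect_allele) == other_allele.upper()


def harmonize(
    original: RiskVariant,
    replication: RiskVariant,
    palindromic_policy: str = "trust",
) -> RiskVariant:
    """Orient a replication record to the original's effect allele.

    Handles the four allele configurations (same orientation, effect/other
    swap, strand flip, strand flip + swap): a swap inverts the OR and
    complements the frequency; a pure strand flip only relabels alleles.
    Irreconcilable alleles raise :class:`HarmonizationError`.  Palindromic
    (A/T, C/G) pairs are strand-ambiguous: the default policy trusts the
    recorded orientation for a shared rsid; ``palindromic_policy="freq"``
    additionally resolves by frequency matching and raises when the minor
    allele frequency is above 0.4 (frequencies too close to 0.5 to decide).
    """
    ea_o = original.effect_allele.upper()
    oa_o = original.other_allele.upper() if original.other_allele else None
    ea_r = replication.effect_allele.upper()
    oa_r = replication.other_allele.upper() if replication.other_allele else None

    ambiguous = is_palindromic(ea_r, oa_r) or (
        oa_r is None and oa_o is None and ea_r != ea_o and _complement(ea_r) == ea_o
    )
    if ambiguous and palindromic_policy == "freq":
        if min(replication.eaf, 1 - replication.eaf) > 0.4:
            raise HarmonizationError(
                f"{replication.rsid}: palindromic with MAF > 0.4; orientation ambiguous"
            )
        same = (replication.eaf < 0.5) == (original.eaf < 0.5)
        return replication if same else _swap(replication, original)

    def matches(x: str | None, y: str | None) -> bool:
        return x is None or y is None or x == y

    # Interpretations in order of preference; same-strand readings first,
    # which is what "trusting the recorded orientation" means for letter
    # pairs a strand flip could also explain (palindromic SNPs).
    if ea_r == ea_o and matches(oa_r, oa_o):
        return replication
    if (oa_o is not None and ea_r == oa_o and matches(oa_r, ea_o)) or (
        oa_o is None and ea_r != ea_o and matches(oa_r, ea_o)
    ):
        return _swap(replication, original)
    c_ea = _complement(ea_r)
    c_oa = _complement(oa_r) if oa_r else None
    if c_ea is not None:
        if c_ea == ea_o and matches(c_oa, oa_o):
            return replace(replication, effect_allele=c_ea, other_allele=c_oa)
        if (oa_o is not None and c_ea == oa_o and matches(c_oa, ea_o)) or (
            oa_o is None and c_ea != ea_o and matches(c_oa, ea_o)
        ):
            return _swap(
                replace(replication, effect_allele=c_ea, other_allele=c_oa), original
            )
    raise HarmonizationError(
        f"{replication.rsid}: alleles {ea_r}/{oa_r} irreconcilable with {ea_o}/{oa_o}"
    )


def _swap(rec: RiskVariant, original: RiskVariant) -> RiskVariant:
    return replace(
        rec,
        effect_allele=original.effect_allele,
        other_allele=rec.effect_allele,
        or_=1.0 / rec.or_,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def assess(
    originals: list[RiskVariant],
    replications: list[RiskVariant],
    alpha: float = 0.05,
    panel: HaplotypePanel | None = None,
    proxy_r2_min: float = 0.7,
    intercept: float = 1.0,
    proxy_map: dict[str, tuple[str, bool]] | None = None,
    m_policy: str = "attempted",
    palindromic_policy: str = "trust",
) -> tuple[list[ReplicationVerdict], dict]:
    """Assess each original variant against the replication table.

    Parameters
    ----------
    originals, replications
        Reported and replication summary statistics.  Replication records
        are matched by rsid; when absent, a proxy is taken from
        ``proxy_map`` (rsid -> (proxy rsid, invert_or)) or searched in the
        panel among replication rsids at ``proxy_r2_min``.  Because allele
        identity cannot orient a record across two different variants, a
        declared proxy carries an explicit ``invert_or`` phase flag; a
        panel-derived proxy is used as recorded.
    alpha, intercept
        Family-wise level and genomic-inflation intercept; each record's P
        is converted to chi-square(1), deflated, and re-thresholded at
        ``alpha / m``.
    m_policy
        "attempted" (default): m = number of originals, matching the
        convention of dividing by the full reported list even when some
        need proxies; "testable": m counts only variants with a usable
        replication record.

    Returns
    -------
    (verdicts, summary) where summary holds n_tested, n_significant,
    n_direction_consistent, pct_significant and the threshold applied.
    """
    if not originals:
        raise ValidationError("assess requires a non-empty originals list")
    rep_by_id = {r.rsid: r for r in replications}
    proxy_map = proxy_map or {}

    matched: list[tuple[RiskVariant, RiskVariant | None, str | None, bool]] = []
    for o in originals:
        rec, proxy, invert = rep_by_id.get(o.rsid), None, False
        if rec is None and o.rsid in proxy_map:
            proxy, invert = proxy_map[o.rsid]
            rec = rep_by_id.get(proxy)
        if rec is None and panel is not None and o.rsid in panel:
            found = ld.best_proxy(
                o.rsid, [r for r in rep_by_id if r in panel], panel, proxy_r2_min
            )
            if found is not None:
                proxy, rec = found[0], rep_by_id[found[0]]
        matched.append((o, rec, proxy, invert))

    n_testable = sum(1 for _, rec, _, _ in matched if rec is not None)
    m = len(originals) if m_policy == "attempted" else max(n_testable, 1)
    threshold = bonferroni_alpha(alpha, m)

    verdicts: list[ReplicationVerdict] = []
    for o, rec, proxy, invert in matched:
        if rec is None:
            verdicts.append(
                ReplicationVerdict(o.rsid, None, None, False, False, testable=False,
                                   note="no replication record or proxy"))
            continue
        if proxy is None:
            harmonized = harmonize(o, rec, palindromic_policy=palindromic_policy)
        else:
            if invert:
                harmonized = replace(
                    rec,
                    or_=1.0 / rec.or_,
                    eaf=None if rec.eaf is None else 1.0 - rec.eaf,
                )
            else:
                harmonized = rec
        p_adj = adjust_p(harmonized.p, intercept)
        same_dir = (
            math.log(harmonized.or_) * math.log(o.or_) > 0.0
        )  # OR exactly 1 on either side counts as inconsistent
        sig = p_adj < threshold and same_dir
        verdicts.append(ReplicationVerdict(o.rsid, proxy, p_adj, same_dir, sig))

    summary = {
        "n_tested": n_testable,
        "n_significant": sum(v.significant for v in verdicts),
        "n_direction_consistent": sum(v.direction_consistent for v in verdicts),
        "threshold": threshold,
        "pct_significant": 100.0 * sum(v.significant for v in verdicts) / len(originals),
    }
    return verdicts, summary
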