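"""Sentinel-eQTL selection and LD-proxy assignment of target genes.

The procedure: restrict published eQTL associations to *cis* records
(SNP within a window of the gene), keep those significant at a Bonferroni
threshold for (genes x independent SNPs) tests, reduce each study's
per-gene eQTL list to approximately independent "sentinel" eQTLs by LD
clumping at low r^2, and finally link a GWAS risk variant to a gene when
it is in strong LD (r^2 above a high threshold) with one of that gene's
sentinels.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from . import ld
from .errors import ValidationError
from .ld import HaplotypePanel
from .types import EqtlRecord, TargetGeneAssignment

logger = logging.getLogger(__name__)


def cis_filter(records: list[EqtlRecord], window_bp: int = 1_000_000) -> list[EqtlRecord]:
    """Keep records with |snp_pos - gene_tss| <= window_bp (inclusive)."""
    out = []
    for r in records:
        if r.snp_pos is None or r.gene_tss is None:
            raise ValidationError(f"eQTL {r.snp}-{r.gene}: positions required for cis filtering")
        if abs(r.snp_pos - r.gene_tss) <= window_bp:
            out.append(r)
    return out


def significance_filter(
    records: list[EqtlRecord],
    n_genes: int = 21472,
    n_indep_snps: int = 1000,
    alpha: float = 0.05,
) -> list[EqtlRecord]:
    """Keep records with P strictly below alpha / (n_genes * n_indep_snps).

    ``n_indep_snps`` is the stipulated number of independent SNPs tested
    per gene in the Bonferroni denominator; it is a convention, not a
    quantity estimated from data.
    """
    if n_genes < 1 or n_indep_snps < 1:
        raise ValidationError("gene and SNP counts must be at least 1")
    threshold = alpha / (n_genes * n_indep_snps)
    return [r for r in records if r.p < threshold]


def select_sentinels(
    records: list[EqtlRecord],
    panel: HaplotypePanel,
    r2_threshold: float = 0.05,
) -> list[EqtlRecord]:
    """Per (study, gene), clump eQTL SNPs by P; clump indices are sentinels.

    Records should already be cis- and significance-filtered.  SNPs absent
    from the panel are dropped with a warning.  When the same SNP carries
    several records for one (study, gene), the smallest P is used.
    """
    groups: dict[tuple[str, str], dict[str, EqtlRecord]] = defaultdict(dict)
    for r in records:
        key = (r.study, r.gene)
        prev = groups[key].get(r.snp)
        if prev is None or r.p < prev.p:
            groups[key][r.snp] = r
    sentinels: list[EqtlRecord] = []
    for (study, gene), by_snp in groups.items():
        variants = [(snp, rec.p) for snp, rec in by_snp.items()]
        clumps = ld.greedy_clump(
            variants, panel, r2_threshold=r2_threshold, window_bp=None, missing="drop"
        )
        for c in clumps:
            sentinels.append(by_snp[c.index_snp])
    return sentinels


def link_targets(
    gwas_snps: list[str],
    sentinels: list[EqtlRecord],
    panel: HaplotypePanel,
    r2_min: float = 0.8,
) -> list[TargetGeneAssignment]:
    """Assign genes to GWAS variants through strong LD with sentinel eQTLs.

    One assignment per (gwas_snp, gene, study) whose best sentinel r^2
    strictly exceeds ``r2_min``; the maximal-r^2 sentinel is reported, r^2
    ties broken by smaller eQTL P.  SNPs absent from the panel are dropped
    with a warning.  Output sorted by (gwas_snp, descending r^2).
    """
    assignments: list[TargetGeneAssignment] = []
    for snp in gwas_snps:
        if snp not in panel:
            logger.warning("GWAS SNP %s absent from panel; skipped", snp)
            continue
        best: dict[tuple[str, str], tuple[float, float, EqtlRecord]] = {}
        for s in sentinels:
            if s.snp not in panel:
                logger.warning("sentinel %s absent from panel; skipped", s.snp)
                continue
            try:
                r2 = ld.pairwise_r2(panel, snp, s.snp)
            except ld.MonomorphicSnpError:
                continue
            key = (s.gene, s.study)
            if key not in best or (r2, -s.p) > (best[key][0], -best[key][1]):
                best[key] = (r2, s.p, s)
        for (gene, study), (r2, _, s) in best.items():
            if r2 > r2_min:
                assignments.append(
                    TargetGeneAssignment(
                        gwas_snp=snp, sentinel_eqtl=s.snp, r2=r2, gene=gene,
                        study=study, tissue=s.tissue, eqtl_p=s.p,
                    )
                )
    assignments.sort(key=lambda a: (a.gwas_snp, -a.r2, a.gene, a.study))
    return assignments


def distinct_genes(assignments: list[TargetGeneAssignment]) -> tuple[int, list[str]]:
    """Count of unique gene identifiers across assignments, plus the list."""
    genes = sorted({a.gene for a in assignments})
    return len(genes), genes
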