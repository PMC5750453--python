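"""Shared domain records.

These are plain validated dataclasses; heavier containers (the haplotype
panel, result tables) live with the modules that own them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass
class RiskVariant:
    """One reported disease association.

    ``eaf`` and ``or_`` are oriented to ``effect_allele``; ``other_allele``
    is optional because curated tables often omit it.  The minor-allele
    frequency is derived, and ``var(g)`` is invariant to which orientation
    was recorded.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    or_: float
    p: float
    eaf: float | None = None
    other_allele: str | None = None
    pmid: str | None = None
    ancestry: str = ""

    def __post_init__(self):
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.rsid}: EAF must be in (0, 1), got {self.eaf}")
        if not self.or_ > 0.0:
            raise ValidationError(f"{self.rsid}: OR must be positive, got {self.or_}")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.rsid}: P must be in (0, 1], got {self.p}")

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class EqtlRecord:
    """One SNP-gene expression association from an eQTL study."""

    snp: str
    gene: str
    p: float
    study: str = ""
    tissue: str = ""
    beta: float | None = None
    snp_pos: int | None = None
    gene_tss: int | None = None

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"eQTL {self.snp}-{self.gene}: P must be in (0, 1], got {self.p}")


@dataclass
class TargetGeneAssignment:
    """A GWAS variant linked to a gene through strong LD with a sentinel eQTL."""

    gwas_snp: str
    sentinel_eqtl: str
    r2: float
    gene: str
    study: str = ""
    tissue: str = ""
    eqtl_p: float = 1.0


@dataclass
class CitationRecord:
    """Gene with allergy co-citation counts before and since a cutoff year."""

    gene: str
    n_before: int
    n_since: int
    cutoff_year: int = 2007

    def __post_init__(self):
        if self.n_before < 0 or self.n_since < 0:
            raise ValidationError(f"{self.gene}: citation counts must be non-negative")
        if self.n_before != int(self.n_before) or self.n_since != int(self.n_since):
            raise ValidationError(f"{self.gene}: citation counts must be integers")


@dataclass
class StudyDesign:
    """Case-control design under the liability-threshold model."""

    n_cases: int
    n_controls: int
    prevalence_K: float
    snp_h2_liab: float = 0.0005
    label: str = ""

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if not (0.0 < self.prevalence_K < 1.0):
            raise ValidationError(f"prevalence K must be in (0, 1): {self.prevalence_K}")
        if not (0.0 <= self.snp_h2_liab < 1.0):
            raise ValidationError(f"SNP liability h2 must be in [0, 1): {self.snp_h2_liab}")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total
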