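"""Pipeline configuration: every named threshold in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Thresholds, constants and input paths for the full pipeline.

    Defaults are the analysis conventions: clumping independence at
    r^2 < 0.05, strong LD at r^2 > 0.8, family-wise alpha 0.05, a 1 Mb cis
    window, a Bonferroni denominator of 21 472 genes x 1000 independent
    SNPs for eQTL significance, a >= 5 co-citation cutoff at year 2007,
    and an LD-score inflation intercept of 1.073 for the replication
    statistics.  Any path left ``None`` falls back to the bundled fixture
    table for that stage.
    """

    clump_r2: float = 0.05
    clump_window_bp: int = 1_000_000
    strong_ld_r2: float = 0.8
    alpha: float = 0.05
    cis_window: int = 1_000_000
    eqtl_gene_count: int = 21472
    eqtl_indep_snps: int = 1000
    min_citations: int = 5
    cutoff_year: int = 2007
    ld_intercept: float = 1.073
    proxy_r2_min: float = 0.7
    snp_h2_liab: float = 0.0005
    snp_based_h2_pct: float = 14.0
    seed: int = 1
    originals_path: str | None = None
    replication_path: str | None = None
    panel_vcf_path: str | None = None
    eqtl_path: str | None = None
    citations_path: str | None = None
    outdir: str = "postgwas_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        checks = [
            (0.0 < self.clump_r2 < 1.0, "clump_r2 in (0, 1)"),
            (0.0 < self.strong_ld_r2 < 1.0, "strong_ld_r2 in (0, 1)"),
            (0.0 < self.alpha < 1.0, "alpha in (0, 1)"),
            (self.cis_window > 0, "cis_window positive"),
            (self.eqtl_gene_count >= 1, "eqtl_gene_count >= 1"),
            (self.eqtl_indep_snps >= 1, "eqtl_indep_snps >= 1"),
            (self.min_citations >= 1, "min_citations >= 1"),
            (self.ld_intercept > 0, "ld_intercept positive"),
            (0.0 <= self.snp_h2_liab < 1.0, "snp_h2_liab in [0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"config: {msg}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**data)
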