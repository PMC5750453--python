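"""Bundled reference tables for the asthma post-GWAS analysis.

Five small TSV tables curated from the published asthma GWAS literature
(European-ancestry studies, 2007-2016) and its UK Biobank replication are
shipped with the package so every pipeline stage runs without external
downloads:

* ``table1`` - the 31 approximately independent reported risk variants
  (identifier, position, effect allele, odds ratio, P, source PMID);
* ``table2`` - replication summary statistics for the same loci in the
  UK Biobank cohort (44 003 self-reported doctor-diagnosed asthma cases,
  336 500 controls), with minor-allele frequency, odds ratio, P and the
  per-SNP liability h2 as originally printed;
* ``table3`` - case-control designs of comparably sized GWAS of five
  diseases, with prevalence and the printed NCP benchmark;
* ``table4`` - sentinel-eQTL target-gene assignments (GWAS SNP, sentinel
  eQTL, r2, gene, study, tissue);
* ``table5`` - gene/allergy-term co-citation counts before and since 2007.

Files are integrity-checked against pinned SHA-256 digests at load time;
a mismatch raises :class:`~postgwas.errors.PackagingError`.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import PackagingError
from .types import CitationRecord, RiskVariant, StudyDesign, TargetGeneAssignment

_CHECKSUMS = {
    "table1.tsv": "c942dba7071336a7b0d29ab21d66ad144cfeb6a753604dfe5c3aa59decb3161c",
    "table2.tsv": "5df6282399327722205ad0a1dfb732e35187515be9af4870702bb38e85325215",
    "table3.tsv": "2ef05710e86cfd58f4b1efc028e20eda917aeba525118590269c615d1587ca7c",
    "table4.tsv": "b246176b9a6cf47360dc9f688105c51f4eb9725b83ed4a1be7186bb3cfacd2c2",
    "table5.tsv": "12c220c15f3714300fd8ef4174da2458acf6e07425683b5f2488a25a3ea3321e",
}

#: Declared LD proxy for the one reported variant (an indel) absent from the
#: replication table: original rsid -> (proxy rsid, r2, invert_or).  The
#: invert flag records the phase: the proxy's recorded effect allele tags the
#: original's *other* allele, so its OR is inverted during harmonization.
PROXIES: dict[str, tuple[str, float, bool]] = {
    "rs200634877": ("rs166079", 0.75, True),
}


def _load(name: str) -> pd.DataFrame:
    raw = resources.files("postgwas").joinpath("data", name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise PackagingError(f"fixture {name} failed its checksum ({digest})")
    return pd.read_csv(io.BytesIO(raw), sep="\t")


@dataclass
class Fixtures:
    """Parsed bundled tables; build with :func:`fixtures`."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    proxy_map: dict[str, tuple[str, bool]] = field(default_factory=dict)

    @property
    def originals(self) -> list[RiskVariant]:
        """The 31 reported risk variants (no frequency printed)."""
        return [
            RiskVariant(
                rsid=r.SNP, chrom=str(r.CHR), pos=int(r.BP),
                effect_allele=r.EA, or_=float(r.OR), p=float(r.P),
                pmid=str(r.PMID), ancestry="European",
            )
            for r in self.table1.itertuples()
        ]

    @property
    def replication(self) -> list[RiskVariant]:
        """UK Biobank replication statistics, MAF used as the frequency."""
        return [
            RiskVariant(
                rsid=r.SNP, chrom=str(r.CHR), pos=int(r.BP),
                effect_allele=r.EA, or_=float(r.OR), p=float(r.P),
                eaf=float(r.MAF), ancestry="European",
            )
            for r in self.table2.itertuples()
        ]

    @property
    def printed_h2_pct(self) -> dict[str, float]:
        return dict(zip(self.table2.SNP, self.table2.H2_PCT_PRINTED))

    @property
    def locus_context(self) -> dict[str, str]:
        ctx = dict(zip(self.table1.SNP, self.table1.CONTEXT))
        ctx.update(zip(self.table2.SNP, self.table2.CONTEXT))
        return ctx

    def designs(self, snp_h2_liab: float = 0.0005) -> list[StudyDesign]:
        return [
            StudyDesign(
                n_cases=int(r.N_CASES), n_controls=int(r.N_CONTROLS),
                prevalence_K=float(r.PREVALENCE), snp_h2_liab=snp_h2_liab,
                label=r.DISEASE,
            )
            for r in self.table3.itertuples()
        ]

    @property
    def printed_ncp(self) -> dict[str, int]:
        return dict(zip(self.table3.DISEASE, self.table3.NCP_PRINTED))

    @property
    def assignments(self) -> list[TargetGeneAssignment]:
        return [
            TargetGeneAssignment(
                gwas_snp=r.GWAS_SNP, sentinel_eqtl=r.EQTL, r2=float(r.R2),
                gene=r.GENE, study=r.STUDY, tissue=r.TISSUE, eqtl_p=float(r.P),
            )
            for r in self.table4.itertuples()
        ]

    @property
    def citations(self) -> list[CitationRecord]:
        return [
            CitationRecord(gene=r.GENE, n_before=int(r.N_BEFORE),
                           n_since=int(r.N_SINCE), cutoff_year=2007)
            for r in self.table5.itertuples()
        ]

    @property
    def printed_groups(self) -> dict[str, int]:
        return dict(zip(self.table5.GENE, self.table5.GROUP_PRINTED))


def fixtures() -> Fixtures:
    """Load and checksum-verify all bundled tables."""
    return Fixtures(
        table1=_load("table1.tsv"),
        table2=_load("table2.tsv"),
        table3=_load("table3.tsv"),
        table4=_load("table4.tsv"),
        table5=_load("table5.tsv"),
        proxy_map={k: (v[0], v[2]) for k, v in PROXIES.items()},
    )
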