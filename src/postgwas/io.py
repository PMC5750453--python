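"""Readers and writers for the package's file dialects.

Canonical tabular dialect: tab-separated values with a header row and "."
for missing fields (CSV accepted on read via ``sep=","``).  Haplotype
panels round-trip through phased VCF (via cyvcf2) or a plain two-file
hap/legend dialect (legend: ``id chrom pos ref alt``; hap: space-separated
0/1 rows, one row per haplotype).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .ld import Clump, HaplotypePanel
from .liability import LiabilityResult
from .replication import ReplicationVerdict
from .types import CitationRecord, EqtlRecord, RiskVariant

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "OR", "P"]


# ---------------------------------------------------------------- sumstats

def read_sumstats(path, sep: str = "\t") -> tuple[list[RiskVariant], list[dict]]:
    """Read a summary-statistics table into validated records.

    Mandatory columns SNP, CHR, BP, EA, OA, EAF, OR, P (PMID optional);
    "." marks a missing OA/EAF/PMID.  Malformed rows are excluded and
    collected into the returned error report rather than silently dropped.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                RiskVariant(
                    rsid=row["SNP"], chrom=str(row["CHR"]), pos=int(row["BP"]),
                    effect_allele=row["EA"],
                    other_allele=None if pd.isna(row["OA"]) else row["OA"],
                    eaf=None if pd.isna(row["EAF"]) else float(row["EAF"]),
                    or_=float(row["OR"]), p=float(row["P"]),
                    pmid=row.get("PMID") if "PMID" in df.columns and not pd.isna(row.get("PMID")) else None,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append({"line": i + 2, "snp": row.get("SNP", "?"), "reason": str(exc)})
    if errors:
        logger.warning("%s: %d malformed row(s) excluded", path, len(errors))
    return records, errors


def write_sumstats(
    variants: list[RiskVariant],
    path,
    liability: list[LiabilityResult] | None = None,
) -> None:
    """Write the canonical TSV; appends VAR_G/H2_PCT when results given."""
    rows = []
    for v in variants:
        rows.append(
            {
                "SNP": v.rsid, "CHR": v.chrom, "BP": v.pos, "EA": v.effect_allele,
                "OA": v.other_allele or ".",
                "EAF": "." if v.eaf is None else repr(v.eaf),
                "OR": repr(v.or_), "P": repr(v.p), "PMID": v.pmid or ".",
            }
        )
    df = pd.DataFrame(rows)
    if liability is not None:
        by_id = {r.rsid: r for r in liability}
        df["VAR_G"] = [f"{by_id[v.rsid].var_g:.6g}" for v in variants]
        df["H2_PCT"] = [f"{by_id[v.rsid].h2_pct:.2f}" for v in variants]
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ panels

def read_panel_vcf(path, unphased: str = "error") -> HaplotypePanel:
    """Load a phased VCF into a haplotype panel.

    Biallelic sites only; sites with missing or unphased genotypes are
    rejected (``unphased="error"``, default) or dropped (``"drop"``).
    """
    from cyvcf2 import VCF

    if unphased not in ("error", "drop"):
        raise ValidationError(f"unphased policy must be 'error' or 'drop': {unphased}")
    ids, chrom, pos, alleles, cols = [], [], [], [], []
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("dropping multi-allelic site %s", v.ID or v.POS)
            continue
        g = np.array(v.genotypes)  # (n_samples, 3): a, b, phased flag
        bad = (g[:, :2] < 0).any() or not g[:, 2].all()
        if bad:
            if unphased == "error":
                raise FormatError(f"{path}: missing/unphased genotypes at {v.ID or v.POS}")
            logger.warning("dropping missing/unphased site %s", v.ID or v.POS)
            continue
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        alleles.append((v.REF, v.ALT[0]))
        cols.append(g[:, :2].reshape(-1))
    vcf.close()
    if not ids:
        raise FormatError(f"{path}: no usable biallelic phased sites")
    return HaplotypePanel(
        snp_ids=ids, chrom=np.array(chrom, dtype=object), pos=np.array(pos),
        alleles=alleles, H=np.column_stack(cols),
    )


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as a minimal phased VCF (haplotypes paired in order)."""
    if panel.n_haplotypes % 2 != 0:
        raise ValidationError("VCF output needs an even number of haplotypes")
    n_samples = panel.n_haplotypes // 2
    samples = [f"S{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(str(x) for x in panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, snp in enumerate(panel.snp_ids):
            ref, alt = panel.alleles[j]
            gts = "\t".join(
                f"{panel.H[2 * i, j]}|{panel.H[2 * i + 1, j]}" for i in range(n_samples)
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_hap_legend(hap_path, legend_path) -> HaplotypePanel:
    """Two-file dialect: legend ``id chrom pos ref alt``; hap = 0/1 rows,
    one row per haplotype, space-separated, one column per legend SNP."""
    legend = pd.read_csv(legend_path, sep=r"\s+")
    for col in ("id", "chrom", "pos", "ref", "alt"):
        if col not in legend.columns:
            raise FormatError(f"{legend_path}: legend missing column {col!r}")
    H = np.loadtxt(hap_path, dtype=np.int64, ndmin=2)
    if H.shape[1] != len(legend):
        raise FormatError(
            f"{hap_path}: {H.shape[1]} columns but legend lists {len(legend)} SNPs"
        )
    return HaplotypePanel(
        snp_ids=list(legend["id"].astype(str)),
        chrom=legend["chrom"].astype(str).to_numpy(dtype=object),
        pos=legend["pos"].to_numpy(),
        alleles=list(zip(legend["ref"].astype(str), legend["alt"].astype(str))),
        H=H,
    )


def write_hap_legend(panel: HaplotypePanel, hap_path, legend_path) -> None:
    pd.DataFrame(
        {
            "id": panel.snp_ids,
            "chrom": [str(c) for c in panel.chrom],
            "pos": panel.pos,
            "ref": [a[0] for a in panel.alleles],
            "alt": [a[1] for a in panel.alleles],
        }
    ).to_csv(legend_path, sep=" ", index=False)
    np.savetxt(hap_path, panel.H, fmt="%d")


# ----------------------------------------------------------------- reports

def write_clump_report(clumps: list[Clump], panel: HaplotypePanel, path) -> None:
    rows = [
        {
            "index_snp": c.index_snp,
            "chrom": str(panel.chrom[panel.index(c.index_snp)]),
            "pos": int(panel.pos[panel.index(c.index_snp)]),
            "index_p": repr(c.index_p),
            "n_members": len(c.members),
            "members": ",".join(c.members),
        }
        for c in clumps
    ]
    pd.DataFrame(rows, columns=["index_snp", "chrom", "pos", "index_p", "n_members", "members"]).to_csv(
        path, sep="\t", index=False
    )


def write_verdicts(verdicts: list[ReplicationVerdict], summary: dict, tsv_path, json_path) -> None:
    pd.DataFrame(
        {
            "SNP": [v.rsid for v in verdicts],
            "PROXY": [v.proxy_used or "." for v in verdicts],
            "P_ADJ": [("." if v.p_adjusted is None else f"{v.p_adjusted:.4g}") for v in verdicts],
            "DIRECTION_OK": [int(v.direction_consistent) for v in verdicts],
            "SIGNIFICANT": [int(v.significant) for v in verdicts],
        }
    ).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)


def read_eqtl_table(path, sep: str = "\t") -> list[EqtlRecord]:
    df = pd.read_csv(path, sep=sep, na_values=["."], keep_default_na=False)
    for col in ("SNP", "GENE", "P"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    out = []
    for r in df.itertuples():
        out.append(
            EqtlRecord(
                snp=r.SNP, gene=r.GENE, p=float(r.P),
                study=str(getattr(r, "STUDY", "")), tissue=str(getattr(r, "TISSUE", "")),
                beta=None if pd.isna(getattr(r, "BETA", float("nan"))) else float(r.BETA),
                snp_pos=None if pd.isna(getattr(r, "SNP_POS", float("nan"))) else int(r.SNP_POS),
                gene_tss=None if pd.isna(getattr(r, "GENE_TSS", float("nan"))) else int(r.GENE_TSS),
            )
        )
    return out


def write_eqtl_table(records: list[EqtlRecord], path) -> None:
    pd.DataFrame(
        {
            "SNP": [r.snp for r in records],
            "GENE": [r.gene for r in records],
            "P": [repr(r.p) for r in records],
            "BETA": [("." if r.beta is None else repr(r.beta)) for r in records],
            "STUDY": [r.study for r in records],
            "TISSUE": [r.tissue for r in records],
            "SNP_POS": [("." if r.snp_pos is None else r.snp_pos) for r in records],
            "GENE_TSS": [("." if r.gene_tss is None else r.gene_tss) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_citations(path, sep: str = "\t", cutoff_year: int = 2007) -> list[CitationRecord]:
    df = pd.read_csv(path, sep=sep)
    for col in ("GENE", "N_BEFORE", "N_SINCE"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return [
        CitationRecord(gene=r.GENE, n_before=int(r.N_BEFORE), n_since=int(r.N_SINCE),
                       cutoff_year=cutoff_year)
        for r in df.itertuples()
    ]


def write_citations(records: list[CitationRecord], groups: list[int], path) -> None:
    pd.DataFrame(
        {
            "GENE": [r.gene for r in records],
            "N_BEFORE": [r.n_before for r in records],
            "N_SINCE": [r.n_since for r in records],
            "GROUP": groups,
        }
    ).to_csv(path, sep="\t", index=False)
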