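"""End-to-end orchestration of the post-GWAS interpretation stages.

The pipeline runs, in order: LD clumping of the reported risk variants
(when a haplotype panel is supplied), replication assessment against the
replication summary statistics, liability-scale variance accounting, NCP
power comparison across study designs, sentinel-eQTL target-gene linking,
and literature classification.  Each stage writes its report to the output
directory and contributes to a headline JSON; a stage failure aborts with
an error naming the stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import eqtl, io, ld, liability, literature, power, replication
from .config import PipelineConfig
from .errors import PostGwasError, StageError
from .fixtures import fixtures

logger = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PostGwasError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the headline report bundle.

    Inputs default to the bundled fixture tables when the corresponding
    path is ``None``; outputs (clump report, verdicts, h2 table, NCP
    table, assignments, classification, headline JSON) land in
    ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fx = fixtures()
    headline: dict = {}

    originals = _read_or_fixture_sumstats(config.originals_path, fx, "originals")
    replications = _read_or_fixture_sumstats(config.replication_path, fx, "replication")
    panel = None
    if config.panel_vcf_path:
        panel = io.read_panel_vcf(config.panel_vcf_path)

    # --- clumping (requires a panel; fixture variants ship pre-clumped) ---
    if panel is not None:
        clumps = _run_clump(originals, panel, config, out)
        headline["n_clumps"] = len(clumps)
    else:
        logger.info("no panel supplied: reported variants treated as pre-clumped indices")

    # --- replication ---
    verdicts, summary = _run_replication(originals, replications, panel, fx, config, out)
    headline["n_tested"] = summary["n_tested"]
    headline["n_significant"] = summary["n_significant"]
    headline["pct_significant"] = round(summary["pct_significant"], 1)

    # --- liability accounting ---
    results, total_pct, median_pct = _run_h2(replications, config, out)
    headline["total_h2_pct"] = round(total_pct, 2)
    headline["median_h2_pct"] = round(median_pct, 2)
    headline["remaining_h2_pct"] = round(
        liability.remaining_h2(config.snp_based_h2_pct, total_pct), 2
    )

    # --- NCP table ---
    headline["ncp"] = _run_ncp(fx, config, out)

    # --- target genes ---
    assignments = _run_link(panel, fx, config, out)
    n_genes, gene_list = eqtl.distinct_genes(assignments)
    headline["n_target_genes"] = n_genes

    # --- literature classification ---
    headline["group_sizes"] = _run_classify(fx, config, out)

    with open(out / "headline.json", "w") as fh:
        json.dump(headline, fh, indent=2)
    return headline


def _read_or_fixture_sumstats(path, fx, which):
    if path is None:
        return fx.originals if which == "originals" else fx.replication
    records, errors = io.read_sumstats(path)
    if errors:
        logger.warning("%s: %d malformed rows excluded", which, len(errors))
    return records


@_stage("clump")
def _run_clump(originals, panel, config, out):
    variants = [(v.rsid, v.p) for v in originals]
    clumps = ld.greedy_clump(
        variants, panel, r2_threshold=config.clump_r2,
        window_bp=config.clump_window_bp, missing="drop",
    )
    io.write_clump_report(clumps, panel, out / "clumps.tsv")
    return clumps


@_stage("replicate")
def _run_replication(originals, replications, panel, fx, config, out):
    verdicts, summary = replication.assess(
        originals, replications, alpha=config.alpha, panel=panel,
        proxy_r2_min=config.proxy_r2_min, intercept=config.ld_intercept,
        proxy_map=fx.proxy_map,
    )
    io.write_verdicts(verdicts, summary, out / "verdicts.tsv", out / "replication.json")
    return verdicts, summary


@_stage("h2")
def _run_h2(replications, config, out):
    results, total_pct, median_pct = liability.summarize_h2(replications)
    io.write_sumstats(replications, out / "h2_table.tsv", liability=results)
    return results, total_pct, median_pct


@_stage("ncp")
def _run_ncp(fx, config, out):
    designs = fx.designs(snp_h2_liab=config.snp_h2_liab)
    rows = {d.label: round(power.ncp(d).ncp) for d in designs}
    with open(out / "ncp.tsv", "w") as fh:
        fh.write("label\tcases\tcontrols\tprevalence\th2_liab\tncp\n")
        for d in designs:
            fh.write(
                f"{d.label}\t{d.n_cases}\t{d.n_controls}\t{d.prevalence_K}"
                f"\t{d.snp_h2_liab}\t{power.ncp(d).ncp:.2f}\n"
            )
    return rows


@_stage("link-genes")
def _run_link(panel, fx, config, out):
    if config.eqtl_path and panel is not None:
        records = io.read_eqtl_table(config.eqtl_path)
        records = eqtl.cis_filter(records, window_bp=config.cis_window)
        records = eqtl.significance_filter(
            records, n_genes=config.eqtl_gene_count,
            n_indep_snps=config.eqtl_indep_snps, alpha=config.alpha,
        )
        sentinels = eqtl.select_sentinels(records, panel, r2_threshold=config.clump_r2)
        gwas_snps = [v.rsid for v in fx.originals] if config.originals_path is None else [
            v.rsid for v in io.read_sumstats(config.originals_path)[0]
        ]
        assignments = eqtl.link_targets(gwas_snps, sentinels, panel, r2_min=config.strong_ld_r2)
    else:
        # fixture mode: the bundled assignments already encode the linking
        assignments = fx.assignments
    rows = [
        {
            "GWAS_SNP": a.gwas_snp, "EQTL": a.sentinel_eqtl, "R2": f"{a.r2:.2f}",
            "GENE": a.gene, "P": f"{a.eqtl_p:.2g}", "STUDY": a.study, "TISSUE": a.tissue,
        }
        for a in assignments
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "target_genes.tsv", sep="\t", index=False)
    return assignments


@_stage("classify-lit")
def _run_classify(fx, config, out):
    records = fx.citations if config.citations_path is None else io.read_citations(
        config.citations_path, cutoff_year=config.cutoff_year
    )
    groups = [literature.classify(r, min_count=config.min_citations) for r in records]
    io.write_citations(records, groups, out / "citation_groups.tsv")
    sizes = literature.group_sizes(records, min_count=config.min_citations)
    return list(sizes)
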