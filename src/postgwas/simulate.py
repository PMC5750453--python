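"""Seeded generators for every input the pipeline consumes.

Three generators cover the study designs the package analyses:

* block-structured haplotype panels with a controllable within-block r^2,
  built by copying a block founder column with a per-site flip probability
  tuned so realized pairwise r^2 between block members approximates the
  target (between-block columns are independent);
* case-control association summary statistics under the liability-threshold
  disease model: liability = sum_j beta_j (g_j - 2 p_j) + e with normal
  residual variance 1 - sum var(g), an individual is a case when liability
  exceeds the upper-K normal quantile, and individuals are drawn until the
  case and control quotas are met (ascertained sampling); per-SNP odds
  ratios and Wald P-values come from the 2x2 allele-count table;
* cis-eQTL expression traits: beta * diploid dosage + normal noise, with
  P-values from per-SNP simple linear regression.

Every generator is a pure function of its arguments including the seed:
identical calls reproduce identical outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SimulationError, ValidationError
from .ld import HaplotypePanel
from .types import EqtlRecord

__all__ = [
    "SimulationTruth",
    "generate_panel",
    "simulate_case_control",
    "simulate_cohort",
    "simulate_eqtl",
]


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic scenario, for planted-truth tests."""

    seed: int
    block_membership: dict[str, int] = field(default_factory=dict)
    planted_r2: float = 0.0
    causal_betas: dict[str, float] = field(default_factory=dict)
    prevalence_K: float = 0.15
    planted_eqtl_genes: dict[str, str] = field(default_factory=dict)


def _flip_prob_for_corr(target_r: float, p: float) -> float:
    """Per-site flip probability giving corr(founder, copy) ~= target_r.

    corr = p(1-p)(1-2f) / sqrt(p(1-p) q(1-q)) with q = p(1-2f) + f,
    monotone decreasing in f on [0, 0.5]; solved by bisection.
    """
    if target_r >= 1.0:
        return 0.0
    if target_r <= 0.0:
        return 0.5

    def corr(f: float) -> float:
        q = p * (1.0 - 2.0 * f) + f
        return p * (1.0 - p) * (1.0 - 2.0 * f) / np.sqrt(p * (1.0 - p) * q * (1.0 - q))

    lo, hi = 0.0, 0.5
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if corr(mid) > target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_panel(
    n_haplotypes: int,
    n_blocks: int,
    snps_per_block: int,
    within_block_r2: float,
    seed: int,
    maf: float = 0.5,
    chrom: str = "1",
    spacing_bp: int = 5_000,
    block_spacing_bp: int = 5_000_000,
    ancestry_label: str = "synthetic",
) -> tuple[HaplotypePanel, SimulationTruth]:
    """Block-LD haplotype panel with planted within-block r^2.

    Each block has a founder column drawn Bernoulli(maf); the remaining
    columns are flips of the founder with per-site flip probability tuned
    so that pairwise r^2 between two non-founder block members is
    approximately ``within_block_r2`` (founder-member pairs then sit at
    about sqrt(within_block_r2)).  Columns of different blocks are
    independent, and blocks are spaced ``block_spacing_bp`` apart so a
    1 Mb clumping window also separates them.

    Returns the panel and a :class:`SimulationTruth` with the SNP-to-block
    map.
    """
    if n_haplotypes < 50:
        raise ValidationError("need n_haplotypes >= 50 for stable r^2")
    if not (0.0 <= within_block_r2 <= 1.0):
        raise ValidationError(f"within_block_r2 must be in [0, 1]: {within_block_r2}")
    if not (0.0 < maf <= 0.5):
        raise ValidationError(f"maf must be in (0, 0.5]: {maf}")
    if maf * n_haplotypes < 10:
        raise ValidationError(
            f"r^2 target infeasible: expected minor-allele count {maf * n_haplotypes:.1f} < 10"
        )
    if n_blocks < 1 or snps_per_block < 1:
        raise ValidationError("need at least one block and one SNP per block")

    rng = np.random.default_rng(seed)
    # copy-copy corr ~= (founder-copy corr)^2, so aim founder-copy at r^(1/2)
    target_r = np.sqrt(within_block_r2) ** 0.5 if within_block_r2 > 0 else 0.0
    f = _flip_prob_for_corr(target_r, maf)

    cols, ids, pos, membership = [], [], [], {}
    for b in range(n_blocks):
        founder = None
        for _ in range(100):  # redraw monomorphic founders
            cand = (rng.random(n_haplotypes) < maf).astype(np.uint8)
            if 0 < cand.sum() < n_haplotypes:
                founder = cand
                break
        if founder is None:
            raise SimulationError("could not draw a polymorphic founder column")
        for j in range(snps_per_block):
            if j == 0 or within_block_r2 >= 1.0:
                col = founder.copy()
            else:
                col = founder ^ (rng.random(n_haplotypes) < f).astype(np.uint8)
            snp = f"sim_b{b}_s{j}"
            cols.append(col)
            ids.append(snp)
            pos.append(1 + b * block_spacing_bp + j * spacing_bp)
            membership[snp] = b
    panel = HaplotypePanel(
        snp_ids=ids,
        chrom=np.array([chrom] * len(ids), dtype=object),
        pos=np.array(pos),
        alleles=[("A", "G")] * len(ids),
        H=np.column_stack(cols),
        ancestry_label=ancestry_label,
    )
    truth = SimulationTruth(seed=seed, block_membership=membership, planted_r2=within_block_r2)
    return panel, truth


def _freqs_and_sampler(source, rng):
    """Allele frequencies, SNP ids and a batch genotype sampler."""
    if isinstance(source, HaplotypePanel):
        p = source.H.mean(axis=0)
        ids = list(source.snp_ids)

        def draw(n):
            i = rng.integers(0, source.n_haplotypes, size=(n, 2))
            return (source.H[i[:, 0]] + source.H[i[:, 1]]).astype(np.int8)

    else:
        p = np.asarray(source, dtype=float)
        if p.ndim != 1 or not ((p > 0) & (p < 1)).all():
            raise ValidationError("allele frequencies must be a 1-D array in (0, 1)")
        ids = [f"snp{i}" for i in range(p.size)]

        def draw(n):
            return rng.binomial(2, p, size=(n, p.size)).astype(np.int8)

    return p, ids, draw


def _beta_array(causal_betas, ids) -> np.ndarray:
    beta = np.zeros(len(ids))
    if isinstance(causal_betas, dict):
        index = {s: i for i, s in enumerate(ids)}
        for snp, b in causal_betas.items():
            if snp not in index:
                raise ValidationError(f"causal SNP {snp!r} not among simulated SNPs")
            beta[index[snp]] = b
    else:
        arr = np.asarray(causal_betas, dtype=float)
        if arr.shape != beta.shape:
            raise ValidationError("causal_betas length does not match SNP count")
        beta = arr
    return beta


def simulate_case_control(
    source,
    causal_betas,
    prevalence_K: float = 0.15,
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
    max_individuals: int = 10_000_000,
) -> pd.DataFrame:
    """Ascertained case-control summary statistics under liability threshold.

    Parameters
    ----------
    source
        A :class:`HaplotypePanel` (diploids formed by drawing haplotype
        pairs with replacement) or a 1-D array of allele frequencies
        (genotypes Binomial(2, p), i.e. linkage equilibrium).
    causal_betas
        Per-SNP liability effects in liability-SD units per allele, as a
        dict (SNP id -> beta) or a full array; sum of planted var(g) =
        2 p (1-p) beta^2 must stay below 1.
    prevalence_K, n_cases, n_controls, seed
        Disease prevalence, sampling quotas (at least 100 each for stable
        estimates) and the RNG seed.
    max_individuals
        Cap on liability draws; exceeding it (tiny K relative to quotas)
        raises :class:`SimulationError`.

    Returns
    -------
    DataFrame with columns SNP, EAF_cases, EAF_controls, OR_hat, P, where
    OR and the Wald P derive from the 2x2 allele-count table (Haldane 0.5
    correction applied when a cell is empty).
    """
    if not (0.0 < prevalence_K < 1.0):
        raise ValidationError(f"prevalence must be in (0, 1): {prevalence_K}")
    if n_cases < 100 or n_controls < 100:
        raise ValidationError("quotas of at least 100 cases and controls are required")
    rng = np.random.default_rng(seed)
    p, ids, draw = _freqs_and_sampler(source, rng)
    beta = _beta_array(causal_betas, ids)
    var_g = float(np.sum(2.0 * p * (1.0 - p) * beta**2))
    if var_g >= 1.0:
        raise ValidationError(f"planted liability variance {var_g:.3f} must be below 1")
    resid_sd = np.sqrt(1.0 - var_g)
    threshold = stats.norm.ppf(1.0 - prevalence_K)
    causal = np.flatnonzero(beta != 0.0)

    m = len(ids)
    case_alt = np.zeros(m)
    ctrl_alt = np.zeros(m)
    have_cases = have_ctrls = drawn = 0
    batch = int(min(max(2_000, 1.2 * (n_cases / prevalence_K)), max(1, 5e7 // m), 1_000_000))
    while have_cases < n_cases or have_ctrls < n_controls:
        if drawn >= max_individuals:
            raise SimulationError(
                f"case/control quotas unmet after {drawn} liability draws "
                f"(K={prevalence_K}); raise max_individuals or the prevalence"
            )
        G = draw(min(batch, max_individuals - drawn))
        drawn += len(G)
        liab = rng.normal(0.0, resid_sd, size=len(G))
        if causal.size:
            liab = liab + (G[:, causal] - 2.0 * p[causal]) @ beta[causal]
        is_case = liab > threshold
        for mask, have, need, acc in (
            (is_case, have_cases, n_cases, case_alt),
            (~is_case, have_ctrls, n_controls, ctrl_alt),
        ):
            take = min(need - have, int(mask.sum()))
            if take > 0:
                acc += G[np.flatnonzero(mask)[:take]].sum(axis=0)
        have_cases = min(n_cases, have_cases + int(is_case.sum()))
        have_ctrls = min(n_controls, have_ctrls + int((~is_case).sum()))

    a, c = case_alt.copy(), ctrl_alt.copy()
    b = 2.0 * n_cases - a
    d = 2.0 * n_controls - c
    empty = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    a, b, c, d = (x + 0.5 * empty for x in (a, b, c, d))
    or_hat = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = np.log(or_hat) / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "SNP": ids,
            "EAF_cases": case_alt / (2.0 * n_cases),
            "EAF_controls": ctrl_alt / (2.0 * n_controls),
            "OR_hat": or_hat,
            "P": np.clip(pvals, np.nextafter(0, 1), 1.0),
        }
    )


def simulate_cohort(
    source,
    causal_betas,
    prevalence_K: float,
    n_individuals: int,
    seed: int = 0,
) -> np.ndarray:
    """Unascertained cohort: boolean case status for n random individuals.

    Used to check that the liability model's empirical prevalence matches
    K without quota sampling.
    """
    if not (0.0 < prevalence_K < 1.0):
        raise ValidationError(f"prevalence must be in (0, 1): {prevalence_K}")
    rng = np.random.default_rng(seed)
    p, ids, draw = _freqs_and_sampler(source, rng)
    beta = _beta_array(causal_betas, ids)
    var_g = float(np.sum(2.0 * p * (1.0 - p) * beta**2))
    if var_g >= 1.0:
        raise ValidationError(f"planted liability variance {var_g:.3f} must be below 1")
    G = draw(n_individuals)
    liab = rng.normal(0.0, np.sqrt(1.0 - var_g), size=n_individuals)
    causal = np.flatnonzero(beta != 0.0)
    if causal.size:
        liab = liab + (G[:, causal] - 2.0 * p[causal]) @ beta[causal]
    return liab > stats.norm.ppf(1.0 - prevalence_K)


def simulate_eqtl(
    panel: HaplotypePanel,
    gene_map: dict[str, tuple[str, float]],
    n_samples: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    study: str = "simulated",
    tissue: str = "simulated",
) -> list[EqtlRecord]:
    """Planted cis-eQTL association records.

    ``gene_map`` maps a causal SNP id to ``(gene, beta)``; expression for
    each gene is beta times the causal diploid dosage plus N(0, noise_sd)
    noise.  Diploids are formed by sequential haplotype pairing (haplotypes
    2i and 2i+1), so ``n_samples`` may not exceed half the panel.  Every
    panel SNP is then tested against each gene by simple linear regression,
    and records carry SNP positions and the gene TSS (placed at the causal
    SNP's coordinate) so they pass through cis filtering.
    """
    if n_samples < 50:
        raise ValidationError("need n_samples >= 50 for stable eQTL estimates")
    if 2 * n_samples > panel.n_haplotypes:
        raise ValidationError(
            f"sequential pairing needs {2 * n_samples} haplotypes, panel has {panel.n_haplotypes}"
        )
    rng = np.random.default_rng(seed)
    G = (panel.H[0 : 2 * n_samples : 2] + panel.H[1 : 2 * n_samples : 2]).astype(float)
    Gc = G - G.mean(axis=0)
    ss_g = (Gc**2).sum(axis=0)
    records: list[EqtlRecord] = []
    n = n_samples
    for causal_snp, (gene, beta) in gene_map.items():
        ci = panel.index(causal_snp)
        y = beta * G[:, ci] + rng.normal(0.0, noise_sd, size=n)
        yc = y - y.mean()
        ss_y = float((yc**2).sum())
        num = Gc.T @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / np.sqrt(ss_g * ss_y)
            beta_hat = num / ss_g
        tss = int(panel.pos[ci])
        for j in range(panel.n_snps):
            if ss_g[j] == 0.0:  # monomorphic in the sampled diploids
                continue
            rj = float(np.clip(r[j], -1.0, 1.0))
            t = rj * np.sqrt((n - 2) / max(1.0 - rj * rj, 1e-300))
            pv = float(np.clip(2.0 * stats.t.sf(abs(t), df=n - 2), np.nextafter(0, 1), 1.0))
            records.append(
                EqtlRecord(
                    snp=panel.snp_ids[j],
                    gene=gene,
                    p=pv,
                    beta=float(beta_hat[j]),
                    study=study,
                    tissue=tissue,
                    snp_pos=int(panel.pos[j]),
                    gene_tss=tss,
                )
            )
    return records
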