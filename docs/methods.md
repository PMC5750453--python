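# Methods

## Linkage disequilibrium and clumping

LD is computed from phased haplotypes, never from genotype correlation:
for SNPs *a*, *b* with alt-allele frequencies `p_a`, `p_b` and joint
alt-alt haplotype frequency `p_ab`,

    r^2 = (p_ab - p_a p_b)^2 / (p_a(1-p_a) p_b(1-p_b)),

the exact squared correlation of the two 0/1 indicator columns. LD at a
monomorphic site is an error, not zero — silently returning 0 would let a
monomorphic "proxy" pass an independence filter.

Clumping is greedy and P-value ordered: visit variants in ascending P;
each unassigned variant becomes a clump index; every remaining unassigned
variant on the same chromosome within the window whose r² with the index
*strictly exceeds* the threshold joins the clump. Defaults: r² threshold
0.05 for independence, a 1 Mb half-window (the window is a convention of
the clumping tools this mirrors, not a biological constant, and is
exposed as a flag; sentinel-eQTL clumping disables it). Equal-P ties are
broken by (chromosome, position, identifier) so output is deterministic.
Variants absent from the panel are dropped with a logged warning by
default (`missing="error"` available).

Proxy search returns the candidate of maximal r² at or above a floor,
ties broken by smaller base-pair distance then identifier. The default
floor is 0.7: strong LD is defined as r² > 0.8 throughout, but the one
curated proxy pair in the bundled tables sits at r² = 0.75, and a floor
of 0.7 admits it while still excluding weakly linked stand-ins. This is a
deliberate policy choice where the two conventions (0.75 accepted, 0.8
"strong") are inconsistent; the flag `proxy_r2_min` overrides it.

## Liability-scale variance explained

A variant with effect-allele frequency *p* and allelic odds ratio *OR*
contributes

    var(g) = 2 p (1-p) (ln OR)^2

to the variance of a logistic-scale disease liability, and its SNP
heritability is `h2 = var(g) / (var(g) + pi^2/3)`, the share of total
liability variance when the residual is standard logistic (variance
pi²/3 ≈ 3.2899). The natural logarithm is used (base-10 reproduces no
published per-variant value), and the denominator is the *sum*
`var(g) + pi^2/3`. Both quantities are invariant under the allele flip
(p → 1-p, OR → 1/OR), so minor-allele frequencies may be supplied
directly. Raw proportions are kept internally; writers round percentages
to two decimals.

Recomputing the bundled 31-variant replication table from its printed
MAF/OR columns reproduces the printed per-variant h² column to ±0.01
percentage points at print precision. The printed values derive from
unrounded odds ratios, so exact per-row equality is not expected; the
recomputed total is 2.49% (rounds to 2.5%) and the recomputed median is
0.055%, which rounds to 0.05% rather than the printed 0.06% — a pure
artifact of odds-ratio rounding in the source table, reported as computed.

`remaining_h2` subtracts the explained total from a genome-wide SNP-based
heritability estimate supplied as an input (default 14%); estimating that
genome-wide figure (LD-score regression, GREML) is out of scope.

## Liability-threshold power

Disease status is modelled as a standard normal liability exceeding the
threshold `T = Phi^-1(1-K)` for prevalence *K*. For a SNP explaining a
share `h2_l` of liability variance, the observed-scale (0/1 trait)
variance share in a case-control sample with case fraction *P* is the
ascertainment-corrected transformation

    h2_obs = h2_l * z^2 * P(1-P) / (K(1-K))^2,   z = phi(T),

and the 1-df association chi-square has non-centrality `NCP = N * h2_obs`,
linear in total sample size. *P* is taken as the sample case fraction
from the case/control counts, never the prevalence. Normal quantile and
density are evaluated in double precision (scipy), with no series
approximations. Power at level alpha is the noncentral chi-square tail
beyond the central critical value.

Against the five benchmark study designs bundled with the package, this
transformation reproduces the rheumatoid-arthritis NCP exactly (77) and
the other four to ±1 (computed 24/39/52/101 versus printed 24/40/52/102);
the residual ±1 is attributed to rounding in the benchmark table and is
asserted at that tolerance, not absorbed. The schizophrenia/asthma ratio
is 2.60 either way.

## Replication assessment

A reported variant replicates when its replication-table record, after
harmonization to the originally reported effect allele, is significant at
`alpha/m` and directionally consistent (same sign of ln OR; OR exactly 1
counts as inconsistent). `m` is the number of originals *attempted* (31
in the bundled analysis), not the number directly typed — matching the
convention of dividing by the full reported list even when one variant
needs a proxy. Test statistics are first deflated by a genomic-inflation
(LD-score) intercept: P → chi²(1) quantile → divide by intercept →
re-evaluate the tail. The threshold is applied to the adjusted P.

Harmonization resolves the four allele configurations (identity,
effect/other swap, strand flip, strand flip + swap); a swap inverts the
OR and complements the frequency, a pure strand flip only relabels.
When only effect alleles are recorded, both are read on the same strand:
equal letters mean identity, different letters mean swap. This is what
"trusting the recorded orientation" means for palindromic (A/T, C/G)
variants, where a strand flip is observationally indistinguishable; the
optional `palindromic_policy="freq"` resolves by frequency matching
instead and refuses records with MAF > 0.4. A declared proxy pair cannot
be harmonized by allele identity at all (the variants differ), so proxy
metadata carries an explicit phase flag stating whether the proxy's
effect allele tags the original's other allele.

## Sentinel eQTLs and target genes

eQTL records are (SNP, gene, P, study, tissue) tuples with positions.
The chain: keep cis records (SNP within 1 Mb of the gene anchor,
boundary inclusive; the anchor is the TSS by default), keep records with
P strictly below `alpha / (n_genes * n_indep_snps)` (defaults 21 472
genes x 1000 independent SNPs, giving 2.3e-9; the 1000 is a stipulated
convention exposed as a parameter, not a computed quantity), then within
each (study, gene) clump the surviving SNPs at r² < 0.05 — the clump
indices are the sentinel eQTLs. A GWAS variant is assigned a target gene
when its maximal r² to any sentinel of that gene strictly exceeds 0.8;
the maximal-r² sentinel is reported, r² ties broken by smaller eQTL P.
Multiple studies supporting the same (variant, gene) pair are all
retained. Distinct-gene counting deduplicates across assignments.

## Literature classification

Genes are classified from co-citation counts with allergy-related terms:
group 1 if cited in at least `min_count` (default 5) publications before
the cutoff year (default 2007), else group 2 if at least `min_count`
since, else group 3. Group 1 takes precedence — a gene well established
before the cutoff stays group 1 regardless of its later count (the
bundled table contains such a gene with only 2 post-cutoff citations).
Literature retrieval itself is out of scope; counts are inputs.

## Synthetic data

`generate_panel` plants block LD: each block has a Bernoulli(maf)
founder column (default maf 0.5) and the other block members are
per-site flips of the founder with flip probability solved (by bisection
on the exact flip-correlation identity) so that *member-member* r²
approximates the requested within-block r²; founder-member pairs then
sit at about its square root. Blocks are 5 Mb apart and independent.
Realized within-block r² is within ±0.1 of target on average at 500+
haplotypes; between-block mean r² is below 0.02. Requested MAFs whose
expected minor-allele count is below 10 are rejected as infeasible for
stable LD.

`simulate_case_control` draws diploids (haplotype pairs with
replacement from a panel, or Binomial(2, p) from supplied frequencies),
forms the liability `sum_j beta_j (g_j - 2p_j) + e` with normal residual
variance `1 - sum var(g)`, thresholds at `Phi^-1(1-K)`, and samples
until the case and control quotas are met (a draw cap raises an explicit
simulation error for infeasibly small K). Per-SNP odds ratios and Wald
P-values come from the 2x2 allele-count table with Haldane 0.5
correction — a deliberate simplification over logistic regression,
matching the allelic-OR scale the var(g) formula consumes. The default
prevalence is 0.15 (asthma). At this prevalence the probit-model OR
inflation factor `z^2/(K(1-K))^2 = 3.34` happens to be close to the
logistic denominator `pi^2/3 = 3.29`, so the logistic-scale h² chain
recovers a planted probit-scale h² of 0.4% to within 0.1 pp (a property
of the high-prevalence regime, verified by test, not a general identity).
Under the null the P-values are uniform and the type-I error at 0.05 is
0.05 ± 0.01 (asserted over seeds 1-5 at 2000 SNPs).

`simulate_eqtl` pairs haplotypes sequentially (no recombination),
generates expression as beta x causal dosage + normal noise, and tests
every panel SNP per gene by simple linear regression; the gene TSS is
placed at the causal SNP so records pass cis filtering.

Every generator is a pure function of its arguments including the seed.
What the generators do **not** emulate: realistic human LD decay,
recombination maps, allele-frequency spectra, imputation error,
covariate structure, or polygenic backgrounds beyond the planted SNPs.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under the stated model, not robustness to every artefact
of real cohort data.

## Problem sizes and numerical choices

Simulation-based tests use 200-2000 haplotypes, quotas of 1000-8000
cases/controls, 2000 null SNPs, and 5-20 seeded replicates; these sizes
give the binomial/Monte-Carlo error bounds asserted in each test while
keeping the default suite fast. Strict inequalities at thresholds
(clumping r², Bonferroni, strong-LD) follow the source conventions;
oracle comparisons in tests avoid thresholds that tiny haplotype counts
can hit exactly, where a strict ">" is float-knife-edged by
construction. Reported thresholds are rounded to two significant figures
for display only.

## Known limitations

- Replication statistics are consumed as summary tables; fitting the
  underlying logistic models to individual-level biobank data is out of
  scope, as are LD-score/GREML heritability estimation, coding-variant
  annotation, colocalization posteriors and literature retrieval.
- The curated tables print MAF rather than signed effect-allele
  frequency; var(g) is invariant to the flip, but the orientation of a
  few near-0.5 variants is ambiguous from the tables alone.
- Single-ancestry LD only: one panel at a time, no meta-LD across
  ancestries, no D'.
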