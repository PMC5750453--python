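# Bundled reference tables

Small curated TSV snapshots of the European-ancestry asthma GWAS literature
(2007-2016) and its UK Biobank replication, so that every pipeline stage runs
offline. All files are plain tab-separated text with a header row and are
integrity-checked by `postgwas.fixtures` against pinned SHA-256 digests.

- `table1.tsv` - 31 approximately independent reported risk variants
  (GWAS-catalog-style curation, clumped at r^2 < 0.05 against a European
  reference panel). Columns: locus index, rsID, chromosome, 1-based GRCh37
  position, gene context, effect allele (`I` marks an insertion allele),
  odds ratio, discovery P-value, source PubMed ID, publication year, and
  whether correlated variants were reported by other GWAS.
- `table2.tsv` - replication summary statistics for the same loci in the UK
  Biobank cohort (44 003 self-reported doctor-diagnosed asthma cases,
  336 500 controls; logistic model with age, sex and chip covariates;
  association statistics adjusted downstream for an LD-score intercept of
  1.073). `rs166079` stands in for the indel `rs200634877` as an LD proxy
  (r^2 = 0.75). `H2_PCT_PRINTED` is the per-SNP liability-scale h2 as
  originally reported, kept for cross-checking the re-computation.
- `table3.tsv` - case/control counts, assumed lifetime prevalence and the
  reported benchmark non-centrality parameter (for a SNP explaining 0.05%
  of liability variance) for five comparably sized disease GWAS.
- `table4.tsv` - sentinel-eQTL target-gene assignments: GWAS SNP, the
  sentinel eQTL in strongest LD (r^2 > 0.8), target gene, eQTL P-value,
  study and tissue. 48 rows, 48 distinct genes.
- `table5.tsv` - counts of publications co-mentioning each candidate gene
  (HGNC symbol or alias) and allergy-related terms, before and since 2007.
  The underlying literature query used the term set
  `asthma OR rhinitis OR eczema OR atopic OR dermatitis OR allergy OR
  allergi* OR hayfever OR "hay fever"` against title/abstract/keyword
  fields; only the resulting counts are shipped, the retrieval itself is
  out of scope. `GROUP_PRINTED` is the originally reported three-group
  placement, kept for cross-checking the classifier.
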