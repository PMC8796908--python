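# poolscan

A comparative Pool-seq genome-scan toolkit for population geneticists
comparing patterns of diversity and divergence across species. Given
pooled variant calls (VCF with per-pool read depths), gene annotations
(GFF3) and a cross-species ortholog map (TSV), it computes:

- **Windowed expected heterozygosity** — per population, H̄E over fixed
  50 kb windows: the sum of per-SNP `H_E = 2p̂(1−p̂)` divided by window
  length, so invariant sites count as zeros.
- **Pool-corrected FST** — a per-SNP method-of-moments ANOVA estimator
  that accounts for the two-stage sampling of Pool-seq (2N allele copies
  per pool, then reads), plus a Hudson cross-check mode. Genome-wide FST
  is the multilocus ratio-of-sums.
- **Top-candidate scan** — SNPs above the species-wide 0.999 FST
  quantile are outliers; a gene is a candidate for local adaptation when
  its outlier count strictly exceeds the 0.999 quantile of
  Binomial(n SNPs in gene, p = 0.001).
- **Null-W convergence test** — candidates from species A are mapped
  through 1:1 orthologs into species B; each ortholog's SNP FST values
  are ranked against 10,000 shared control SNPs (Mann–Whitney W → Z),
  placed in the empirical Z distribution of non-candidate orthologs, and
  Bonferroni-corrected.
- **Cross-species comparison** — Spearman correlations of per-gene FST
  and H̄E over ortholog pairs, a population-by-population H̄E correlation
  matrix, and shared-extreme (5%/95% tail) gene counts.

A fully seeded synthetic-data module (Balding–Nichols allele
frequencies, two-stage pooled read sampling, planted selected and
convergent genes, ortholog maps with 1:many contamination) makes every
stage testable without real data.

## Worked example

Run the bundled two-species scenario end to end (simulates a
threespine-stickleback-like and a tubesnout-like dataset, 5,000 SNPs and
200 genes each, then filters, scans and compares them):

```sh
poolscan run --config run.yaml
```

with `run.yaml`:

```yaml
seed: 3
out_dir: results/demo
simulate:
  preset_a: threespine
  preset_b: tubesnout
  convergent_fraction: 0.0
```

The run writes per-stage tables (`filtered_*.tsv`, `windows_*.tsv`,
`fst_*.tsv`, `genes_*.tsv`, `candidates_*.tsv`, `nullw_*.tsv`,
`comparison.tsv`) plus `manifest.json`, which for this seed reports:

```
analyse_threespine:  global_fst 0.1361   mean_window_he ~0.00155   n_top_candidates 0
analyse_tubesnout:   global_fst 0.1157   mean_window_he ~0.00158   n_top_candidates 0
ortholog_filter:     220 input pairs -> 154 clean 1:1 pairs kept
comparison:          gene-level FST rho -0.08 (p 0.32), He rho -0.05 (p 0.51), n 154
```

Interpretation: the multilocus FST estimates recover the generating
baselines (0.14 and 0.12) within sampling error of a 5,000-SNP genome;
with no planted selection the top-candidate scan calls nothing; and the
two independently simulated species show no gene-level correlation —
the expected outcome under neutrality.

Each stage is also available as its own subcommand (`simulate`,
`filter`, `diversity`, `genes`, `orthofilter`, `topcand`, `nullw`,
`compare`, `plot`) for working with intermediate tables; see
`poolscan <cmd> --help`.

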