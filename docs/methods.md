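# Methods

## Scope and data model

poolscan analyses pooled whole-genome sequencing (Pool-seq) of
population samples: each sequencing library is DNA from many diploid
individuals of one population, so allele frequencies must be estimated
from read counts, never from genotypes. The atom of the pipeline is a
biallelic site with per-pool (ref, alt) read counts; pools carry a
haploid sample size 2N (N diploids). All internal coordinates are
0-based half-open; VCF (1-based) and GFF3 (1-based closed) are converted
at the I/O boundary so interval arithmetic for windows and genes is
uniform.

The VCF depth convention is auto-detected: standard `AD` (ref,alt in one
field) or VarScan-style separate `RD`/`AD` single-value fields. Genotype
calls in the VCF are ignored by design.

## SNP filtering

A site passes when all of the following hold, evaluated in this fixed
order (the first failing rule is the one reported): biallelic; total
depth across pools ≥ 50; site quality ≥ 20; pooled minor-allele
frequency ≥ 0.01; minor-allele reads ≥ 2. The minor-allele frequency is
computed from counts summed over every pool of the species and folded to
`min(f, 1−f)` — the behaviour of a multi-sample caller run on a combined
pileup. Coverage is summed across pools by default: for balanced pools
this is the "every individual sequenced at least once" reading of the
coverage floor; a stricter per-pool mode is available
(`per_pool_coverage`). The filter report satisfies
`passed + Σ removed = total` by construction.

## Windowed expected heterozygosity

Per SNP and pool, `H_E = 2p̂(1−p̂)` with the plug-in read frequency p̂;
no depth unbiasing is applied (windowed H̄E is empirically insensitive
to depth at the coverages targeted here, ~2N per pool). Windows tile
each chromosome from position 0 with width 50,000 bp (default); window
H̄E is the sum of member-SNP H_E divided by the *full window length*, so
invariant sites enter as zeros. A trailing partial window uses its
actual length; an optional callable-sites BED mask replaces the
denominator with callable base pairs. This makes the decomposition
exactly conservative: Σ(window H̄E × window length) equals the per-SNP
H_E total per pool, which the tests assert to machine precision.

## FST

Pool-seq has two sampling stages: 2N allele copies drawn from the
population, then reads drawn (with replacement) from those copies. With
pool haploid sizes `n_i`, depths `c_i` and read frequencies `p̂_i`,

    a_i  = (n_i + c_i − 1) / (n_i c_i)
    π̂_i = p̂_i (1 − p̂_i) / (1 − a_i)        # unbiased for p_i(1−p_i)
    Num  = (p̂_1 − p̂_2)² − a_1 π̂_1 − a_2 π̂_2
    Den  = (p̂_1 − p̂_2)² + p̂_1(1−p̂_1) + p̂_2(1−p̂_2)

Num and Den are unbiased for the numerator `(p_1−p_2)²` and denominator
`p_1(1−p_2)+p_2(1−p_1)` of pairwise FST in the Hudson parameterisation,
where the expectations are over both sampling stages; under
Balding–Nichols differentiation E[Num]/E[Den] = F for every ancestral
frequency. Per-SNP FST is Num/Den (NaN when both pools are fixed for the
same allele, i.e. Den = 0); negative values are retained — clamping
would bias outlier quantiles.

The genome-wide estimate is the multilocus ratio of sums Σ Num / Σ Den.
This matters: the arithmetic mean of per-SNP ratios is strongly biased
toward zero (we measure ≈0.31 at true F = 0.49 for pools of 50 at depth
100), while the ratio-of-sums recovers F within ±0.005 across the range
0.02–0.49 at 10⁵ SNPs. Per-SNP averages are still reported as
descriptive summaries (mean ± SE), matching how per-SNP genome scans are
usually tabulated, but parameter recovery is validated on the
ratio-of-sums.

Two cross-check estimators are provided: Hudson with read-depth
correction only (`p̂(1−p̂)/(c−1)` terms; its residual bias is the pool
term `(1−F)/n`, negligible when depth ≫ pool size), and the naive
plug-in with no correction, whose depth-dependent inflation demonstrates
why the pool correction exists. Multi-pool species are analysed as
designated north–south pool pairs (all north × south combinations); the
per-SNP species value is the mean over pairs.

## Quantiles

All empirical quantiles use the nearest-rank rule: the ⌈nq⌉-th smallest
value (R's `quantile type = 1`). The rank product is rounded to 9
decimals before the ceiling so binary float dust cannot shift a rank
(1000 × 0.999 must give rank 999, not 1000). SNP outliers are values
*strictly above* the 0.999 quantile, so 1,000 distinct values yield
exactly one outlier.

## Top-candidate scan

With outlier probability fixed at the nominal p = 0.001 (not the
realised outlier fraction), a gene with n SNPs is a candidate when its
outlier count strictly exceeds the smallest k with
`CDF_Binom(n, 0.001)(k) ≥ 0.999`. SNPs with missing FST are excluded
from both n and the outlier count; genes without SNPs are never
candidates. Because the per-gene false-positive rate is ≤ 0.001 by
construction, neutral genomes yield candidate fractions ≤ 0.002
(asserted over 2,000 genes).

## Null-W convergence test

Direction is explicit: candidates are identified in species A and FST is
evaluated in species B. One set of 10,000 control SNPs is drawn without
replacement from species B's non-missing per-SNP FST values and shared
by every gene in the run. For each gene, W is the Mann–Whitney statistic
of its SNPs versus the controls (ties as ½) and
`Z = (W − n₁n₂/2) / sqrt(n₁n₂(n+1−T)/12)` with the standard tie
correction `T = Σ(t³−t)/(n(n−1))` and no continuity correction. The test
is one-sided on high Z (selection elevates FST in the second species).

The null distribution is the Z of all orthologous *non-candidate* genes
(deterministic; a `random_k` subset is available). Empirical p-values
use the add-one estimator `p = (1 + #{null Z ≥ z}) / (1 + N_null)` so
p > 0 always, then Bonferroni correction over the number of test genes
at α = 0.05. Both directions (A→B and B→A) are run by the pipeline.

## Ortholog filtering

In fixed order: (1) drop pairs with mapping quality < 80 or percent
identity < 90; (2) drop every pair whose gene occurs in more than one
*surviving* pair (quality-first ordering maximises retained 1:1 pairs);
(3) drop pairs whose gene shares any base pair with another annotated
gene of its species. The output is a bijection between gene sets.

Gene-level H̄E is the gene's majority-window score (largest base-pair
overlap; exact ties go to the lower-coordinate window). Neighbouring
genes therefore share window values — accepted pseudoreplication that
can only overstate the significance of a true cross-species correlation,
i.e. it is conservative for the negative results the comparison module
is designed to detect.

## Cross-species comparison

Species pairs are compared over their filtered 1:1 orthologs: Spearman
rank correlation (midranks, t-approximation p-value) of per-gene mean
FST and of per-gene H̄E (first averaged across each species'
populations). The population-level H̄E matrix correlates windows
directly within a species; across species, windows are not homologous,
so window scores are projected onto genes and matched through the
ortholog map — the only projection consistent with the gene-level H̄E
assignment above. Shared-extreme counts use the per-species 0.95/0.05
nearest-rank thresholds over the matched set, strict inequalities on
both sides.

## Synthetic data

The generator is the package's testbed and defines its reference
conditions. Per SNP: ancestral frequency p₀ ~ Uniform(0.05, 0.95);
population frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) (Balding–Nichols:
mean p₀, variance F p₀(1−p₀)); pool counts by the same two-stage process
the estimator corrects for — 2N copies binomially, then reads ~
Binomial(Poisson(depth), pool fraction). Depth defaults to 2N reads per
pool, the study-style "each chromosome once" target. Site quality is
Uniform(30, 90), comfortably above the quality filter, so filtering
exercises mainly the frequency rules. SNPs are unlinked: all downstream
statistics are marginal per SNP or per gene, so linkage disequilibrium —
which in real data clusters outliers and is part of why the Null-W test
works well on linked architectures — is deliberately not modelled, and
passing tests say nothing about LD-driven clustering in real genomes.
Genes are evenly spaced and non-overlapping; real annotations with
overlapping genes are handled by the ortholog filter instead.

Species presets mirror the three study-species regimes qualitatively:
two-pool moderate differentiation (threespine-like F = 0.14, pools of
52/51; tubesnout-like F = 0.12, pools of 44/50) and a bottlenecked
four-pool scenario (ninespine-like F = 0.49, sparse low-frequency
variation, hence roughly tenfold lower H̄E). Ortholog maps are built
index-to-index with a configurable 1:many fraction (extra cross-links
that break the 1:1 filter), identity ~ Normal(94, 3) clipped to
[70, 100] and mapping quality a 90/10 mixture of Uniform(80, 100) and
Uniform(40, 80), so both filter arms are exercised; the truth table
records exactly which pairs a correct filter must keep. Convergent genes
are planted only on clean 1:1 pairs, with elevated F in both species.

## Validation scenarios and problem sizes

The `evaluation` module fixes the scenarios the test suite and
`scripts/acceptance.py` run:

- *FST recovery*: 10⁵ SNPs, two pools of 50 diploids at depth 100,
  F ∈ {0.02, 0.12, 0.14, 0.49}; recovery within ±0.02 (measured ±0.001)
  and null bias within ±0.01.
- *Top-candidate power*: 200 genes of 2 kb, one SNP per 50 bp (~36 SNPs
  per gene), 2% of genes planted at 4 × baseline F (0.48 over 0.12).
  The planted fraction is kept small deliberately: planted SNPs compete
  for the genome-wide 0.999 quantile, and planting ≳5% of genes pushes
  the outlier threshold into the planted distribution itself, which is
  also why saturated real genomes (the ninespine regime, where most
  SNPs approach fixation) yield no usable outliers.
- *Null-W*: 1,000 genes per species, 40,000 SNPs, 10,000 controls.
  Calibration: 20 null replicates, expecting zero Bonferroni hits in
  ≥ 18; p-value uniformity checked by KS < 0.1 over 300 exchangeable
  test genes. Power: 1% of genes planted at F = 0.6 in both species,
  family-wise detection in ≥ 80% of replicates.

These sizes keep a full validation run around one minute on one CPU
while leaving each check comfortable statistical margin.

## Numerical and degenerate-input conventions

Zero-depth pools give missing frequencies; sites fixed in both pools for
the same allele give missing FST; genes without SNPs have missing mean
FST and never become candidates; constant score vectors make Spearman's
ρ undefined (flagged, not zeroed). Empty inputs raise errors for
quantiles and outlier flagging, and produce zeroed reports for the
filter. All stochastic components take explicit seeds; rerunning any
pipeline config reproduces every output table byte-identically.

## Known limitations

No linkage, no recombination-aware null model, no window-based (non
genic) clustering of outliers; per-SNP FST for multi-pool species is a
mean over north–south pairs rather than a joint multi-population
estimator; the H̄E window denominator assumes fully callable windows
unless a mask is supplied; exact numerical equality with any particular
external FST implementation is not claimed — the estimator is validated
by its sampling properties instead.
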