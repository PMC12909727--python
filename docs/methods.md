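# Methods

This note documents the statistical procedures implemented in hapdiv, the
defaults and why they were chosen, the synthetic-data model behind the test
suite, and known limitations.

## Variant hard-filtering

`apply_filters` keeps a site when QUAL ≥ 30, INFO/DP ≥ 10, INFO/MQ ≥ 40, the
site is biallelic and both alleles are single-base substitutions. All
thresholds are **inclusive**: "below 30" is rejected, so a site at exactly
30 survives; the tests pin this boundary convention. Sites lacking a DP or
MQ annotation fail the corresponding filter by default (conservative);
`FilterCriteria(missing_annotation_passes=True)` passes them through
instead. Multiallelic records are dropped whole, never split into
pseudo-biallelic records. Filtering is idempotent and commutes with region
extraction; both are property-tested.

Coordinates are 1-based fully-closed everywhere (VCF convention), including
`GenomicInterval` and all window reports; BedGraph output converts to
0-based half-open at write time.

## Haplotype construction

A haplotype is the concatenation of a sample's alleles at the retained
variant columns — not the full genomic sequence. `site_positions` retain the
genomic coordinate of each column, which keeps fixtures small while
preserving the locus context. Missing genotypes become `N`; heterozygous
genotypes are resolved by `het_policy` (default `N`, since inbred rice lines
are effectively homozygous and a residual het usually reflects a calling
artefact; `ref`/`alt`/`iupac` are available).

Collapsing partitions samples by exact sequence identity. Samples whose
sequence contains `N` or `-` are excluded and reported separately by default
(`missing_policy="pairwise"` instead assigns them to the first compatible
haplotype under pairwise-complete matching). Numbering is H1, H2, … by
descending carrier count with ties broken by first occurrence; the count
anchoring matches the field convention of naming the most frequent
haplotype H1. Phenotype labels and any Sanger-typed indel genotype enter as
a metadata TSV; they are never inferred from the SNP sequence, because a
hard-filtered VCF excludes the very indel one may care about.

## Statistical-parsimony network

Pairwise distance is the count of columns where both bases are unambiguous
and differ. The network is built Kruskal-style over all pairs with distance
≤ the connection limit, processed in ascending distance tiers; within a
tier, every edge joining components that were distinct at the tier's entry
is retained. Keeping ties makes the result a minimum-spanning *network*
(reticulations possible) rather than a tree, which is what TCS and PopArt
draw. The edge set always contains a minimum spanning forest of the
thresholded distance graph (brute-force-verified on small instances), and
the construction is invariant to input order.

Unsampled intermediate haplotypes (median vectors) are not inserted as
nodes; a multi-step edge simply carries its step count. Intermediates are
cosmetic for the analyses supported here.

The default connection limit is the maximum observed pairwise distance
(connect everything; appropriate for a short locus with few steps). The
optional parsimony limit is the largest j with parsimony probability
≥ 0.95, where the probability that two sequences of length m differing at
j sites are separated by exactly j mutations is computed under a
finite-sites Jukes–Cantor model: each site carries Poisson(λ) mutations on
the path joining the sequences, λ is profiled at its MLE from the observed
divergence (j/m = (3/4)(1 − e^(−4λ/3))), and

P(parsimony) = [λe^(−λ)/(j/m)]^j · [e^(−λ)/(1 − j/m)]^(m−j).

This is the package's own reconstruction of the statistical-parsimony
criterion (the classical software's internal constants are not published in
a reusable form); it is deterministic, ≥ 1, non-decreasing in m, and
decreasing in the confidence level. For a 2,000-column alignment at 95%
confidence it gives a limit of 14 steps, in the range the classical tools
report for alignments of this size.

## Diversity statistics

All alignment statistics use **complete deletion**: columns containing any
`N` or `-` are removed before counting, giving the comparable length L.

- S: retained columns with ≥ 2 distinct bases.
- Watterson's θ per site: S/(a₁L), a₁ = Σ_{i=1}^{n−1} 1/i.
- π per site: mean pairwise differences over all C(n,2) pairs, divided by L.
- Tajima's D: (π_total − S/a₁)/√(e₁S + e₂S(S−1)) with the classical
  constants (a₂, b₁, b₂, c₁, c₂, e₁, e₂). Conventions: D = 0 when S = 0
  (the natural report for an invariant group, e.g. a two-sample group with
  identical sequences where every statistic is zero); D = NaN when S > 0
  but the variance term vanishes — at n = 2, a₁ = 1 forces π_total = S and
  e₁ = 0, so the statistic is 0/0 and genuinely undefined.

The windowed estimator is π̂_w = Σ_{SNP ∈ w} 2p̂q̂ / w over non-overlapping
windows (default 10 kb) tiling the scanned interval, computed from allele
frequencies over non-missing calls. It deliberately **omits** the n/(n−1)
small-sample correction — this is the estimator a VCFtools-frequency
workflow produces — and `window_pi(..., sample_size=n)` applies the
correction when wanted. For haploid samples the two are related exactly by
π_total = n/(n−1)·Σ2pq, which the tests verify on random fixtures.
`flank_scan` extends a gene interval by a flank (default 400 kb each side)
and tiles it; per-group tracks come from restricting the genotype columns
to a sample subset. A trailing partial window is truncated at the interval
end and logged.

## Segregation tests

Pearson's χ² goodness of fit with expected counts N·wᵢ/Σw, df = k − 1, and
upper-tail p-values via the regularized incomplete gamma function Q(df/2,
χ²/2). No continuity correction by default: the classical reported value
for 31:9 against 3:1 (χ² = 0.1333, p = 0.715) is the uncorrected statistic,
and Yates' correction would change it; `yates=True` enables the correction.
Phenotype prediction from genotype uses complete dominance: carriers of at
least one functional allele are positive, only the loss-of-function
homozygote is negative.

## Synthetic-data model

The generators define the study conditions for the test suite:

- **Coalescent alignments**: standard neutral coalescent (pairwise merging
  at rate k(k−1)/2 in units of 2N generations), infinite-sites mutation at
  rate θ/2 per unit branch length, each mutation at a fresh uniformly drawn
  column. When more mutations arise than there are columns the simulator
  fails loudly rather than truncating. Calibration targets: E[S] = θa₁,
  E[π_total] = θ, E[D] ≈ 0; the suite checks these at n = 20, θ = 5 over
  2,000 replicates (5% tolerance, |mean D| < 0.15).
- **VCF generator**: haploid-equivalent genotypes, Bernoulli(freq) per
  sample (inbred-line model; `diploid=True` draws alleles independently for
  het-policy testing); QUAL/DP/MQ drawn comfortably above the filter
  thresholds; `inject_violations=True` appends five records each failing
  exactly one criterion.
- **F₂ populations**: multinomial(¼, ½, ¼) genotypes, dominant phenotype
  map. 40 plants is the default scale of an F₂ greenhouse population. The
  type-I error of the χ² test at true 1:2:1 with n = 40 is 5.8% over
  10,000 replicates — the mild inflation is the usual discreteness of the
  statistic at moderate n, within the 5% ± 1.5% calibration band.
- **Star fixtures**: a core haplotype with satellites at specified
  mutational distances on disjoint columns (distances exactly additive),
  replicated to specified counts. The default spectrum (9 haplotypes over
  126 samples, top counts 61 and 50, satellites 1–3 steps out) emulates
  the skewed frequency spectrum typical of a domestication locus.

Seeding: every generator is a pure function of its seed; a master seed fans
out via `numpy.random.SeedSequence.spawn`, so reruns are bitwise identical.

What the synthetic data does **not** emulate: recombination, migration,
selection, demography, linkage between sites in the VCF generator,
sequencing-error structure in quality annotations, and real missing-data
patterns. Passing calibration therefore demonstrates correctness of the
estimators under neutrality, not robustness of inference on real
resequencing data; genome-scale results from deposited reads require the
full upstream alignment/calling pipeline, which is out of scope here.

## Problem sizes

The default suite uses 2,000 coalescent replicates (n = 20, L = 400),
5,000 two-sample replicates, 500 fuzzed oracle cases (≤ 6 sequences), and
10,000 simulated F₂ populations; the whole run takes well under a minute on
one core. These sizes put Monte-Carlo standard errors comfortably inside
the asserted tolerances while keeping iteration fast.

## Known limitations

- The parsimony connection limit is a principled reconstruction, not a
  re-derivation of the original software's exact output; for short loci the
  default max-distance limit sidesteps the question entirely.
- Window tracks are descriptive; no sweep-model fitting or significance
  envelope is provided.
- The VCF writer emits minimal VCF 4.2 (GT only, DP/MQ INFO) — enough for
  round-tripping the pipeline's own outputs, not a general-purpose writer.
- Mean-pairwise π is quadratic in sample count; fine for hundreds of
  samples at locus scale, not intended for genome-wide matrices.
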