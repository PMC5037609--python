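# Methods

## Coordinate model and I/O

All internal coordinates are 0-based half-open; BED-family formats are
native, GTF (1-based inclusive) and WIG (1-based) are converted at the
I/O boundary only. Chromosome names match by exact string comparison,
with an optional alias table (`{"chr2L": "2L"}`) for dialect drift.
Gene models are reduced to one union span per `gene_id`; the TSS is the
span start on `+` and span end − 1 on `−`. Aligned reads are consumed
as tagAlign/BED6 (a pandas fast path handles full samples); BAM is not
required anywhere.

## Coverage and enrichment

Reads are extended directionally to the fragment length L (estimated,
when not given, as the strand cross-correlation-maximizing shift in
50–500 bp) and piled into per-base fragment-overlap depth. Enrichment
is the ratio of depth tracks each scaled to genome mean 1
(`depth · G / (N·L)`), i.e. normalized for read count and fragment
size; a pseudocount ε keeps zero-input bases finite. ε defaults to a
quarter-fragment depth floor, 0.25·G/(N_in·L_in), chosen so a single
stray input fragment cannot dominate a window; with ε = 0, zero-input
bases are reported as undefined (NaN), never infinite. Metapeak
profiles average per-base enrichment at each offset relative to a
summit set and are smoothed with a centered 31-bp moving average
(shrinking at profile edges); read-per-million profiles are reported
unsmoothed.

## Candidate windows

Peaks below 2-fold enrichment are discarded; the rest are reduced to
their summit with a 201-bp core (summit ± 100) and a 1-kb counting
window [summit − 500, summit + 500). For even widths the tie breaks
toward the left. TSS distance is measured from the summit (all other
geometry in the design is summit-anchored); the location classes are
TSS (< 1 kb), intragenic, and intergenic. Random non-TSS regions —
the conservation null — are sampled uniformly with midpoints ≥ 1 kb
from every TSS, and fail loudly if the annotation would force > 99%
rejection.

## The negative-binomial differential test

Counts are fragments overlapping the 1-kb window by ≥ 1 bp (a fragment
spanning two windows counts in both). The model is
K_ij ~ NB(s_j μ_ic, α_i):

- **Size factors** s_j: median over all-nonzero regions of
  count/geometric-mean (median-of-ratios); total-count fallback when no
  region is all-nonzero.
- **Dispersions** α_i: method-of-moments within each condition,
  α_c = (s²_c − μ_c)/μ_c², combined across conditions with df weights
  and clipped at 0. A mean–dispersion trend α(μ) = a₀/μ + a₁ is fitted
  by least squares with one pass of 4×-residual trimming (the raw MoM
  estimates are χ²-like with a heavy right tail at 1–3 residual df).
  Each region's estimate is then shrunk toward the trend on the log
  scale with weight w = d/(d + d₀), d the residual df and d₀ = 2, and
  **floored at the trend**: with two or three replicates a
  below-trend moment estimate is indistinguishable from sampling noise,
  and propagating it would understate the standard error and inflate
  the false discovery rate. Only excess dispersion above the trend is
  (partially) retained. This floor is the one materially opinionated
  choice in the module; empirically it keeps the null type-I error of
  the Wald test inside [0.035, 0.065] at nominal 0.05 while planted
  3-fold effects remain detectable at > 90% sensitivity.
- **Wald test**: condition means are means of normalized counts; a +0.5
  pseudocount enters only when a condition mean is zero. The delta
  method on log2 of an NB mean gives
  se² = (1/ln2)²·[1/(n_A μ_A) + α/n_A + 1/(n_B μ_B) + α/n_B];
  p = 2(1 − Φ(|log2fc/se|)). All-zero regions are untestable (p = NA)
  and excluded from the BH denominator.
- **BH**: literal step-up, q_(i) = min_{j≥i} m·p_(j)/j, NA-preserving.
  Independent filtering (a baseMean floor before BH) exists behind a
  parameter but is off by default.

Calls at q < 0.01: ME when log2fc > 0 (condition A = the
mesoderm-like tissue), DEE when < 0; everything else forms the
non-differential control group used by every downstream comparison.

## Gene assignment and naming

Active genes have FPKM ≥ 5 (inclusive) in at least one of the two
tissues. Rank-1 assignment prefers an active gene overlapping the core
(ties by summit-to-TSS distance), else the nearest active TSS; ranks
2..k follow by TSS distance. Names are `<gene>-<ME|DEE>[-TSS]<k>`,
numbered along the chromosome per (gene, type), so naming is a
deterministic bijection. Concordance asks whether the rank-k gene is
differentially expressed in the tissue the call predicts, against the
control-group fraction, via a one-sided chi-squared realized as the
signed pooled-proportion z (z² is exactly the 2×2 chi-squared without
continuity correction). Differential-expression calls are taken from
the input table, never recomputed.

## Motif engine

Backgrounds are Markov models (default order 0, configurable to 3) with
add-one smoothing, symmetrized by counting each sequence together with
its reverse complement. Scanning scores every window on both strands
as Σ log2(pwm/bg) with PWM probabilities floored at 1e-4; the hit
p-value Pr(score ≥ s | background) comes from exact dynamic programming
over per-position scores rounded to 1e-3-bit bins (the same binning is
used to accumulate window scores for thresholding, while reported
scores stay exact). Windows containing N are skipped. The default hit
threshold is p ≤ 1e-4. Presence (≥ 1 hit per 201-bp core) feeds
one-sided two-proportion tests in both directions, BH-corrected per
direction. Significant motifs are collapsed into groups when more than
10% of occurrences overlap (denominator: the rarer motif's hit count,
so a rare sub-motif of a common motif still groups; any-strand overlap
by default); the lowest-p member represents the group.

## Conservation

Per-base scores in [0, 1] with NaN for uncovered bases; interval means
exclude NaNs and report coverage. Motif-vs-core uses a paired one-sided
Wilcoxon signed-rank (pooling all instances of a motif within one core
before averaging; zero differences dropped; < 5 informative pairs ⇒
NA). Enhancers-vs-random uses a one-sided rank-sum. Exact null
distributions are used up to n = 25 when the groups share no tied
values; otherwise the normal approximation with midrank tie correction.
All-identical inputs return p = 0.5 (no evidence either way).

## TF occupancy and confidence groups

Per enhancer and factor, the local summit is the argmax of IP coverage
within the core (ties leftmost) and the occupancy is the normalized
IP/input fold over a 201-bp window centered there. The cascade first
excludes calls overlapping known enhancers, calls whose gene is
strictly highest in the third (neurectoderm-proxy) condition, and calls
whose acetylation tissue contradicts the gene's expression tissue; the
survivors go to Dl (≥ 3×), Twi (≥ 5× with Dl < 3×), Mad (≥ 3×) or
Zen (≥ 3× with Mad < 3×). "At least" thresholds are inclusive,
"less than" strict. Heatmap display values map fold 1 → 0 and the 98th
percentile (linear interpolation) → 1, clamped.

## Synthetic data generator

The generator emits the full design with known truth. Geometry: one
chromosome; differential enhancers alternate ME/DEE in gene blocks
(adjacent gene TSS 2.5 kb from the summit, so distal), non-differential
candidates tile 1-kb slots in a separate section, and small sets sit
< 1 kb from a TSS or inside a gene body to exercise the location
classes. Signals: H3K27ac fragments are centered at summit ± 330 bp
with 60-bp Gaussian jitter — reproducing the bimodal flanking profile —
with per-enhancer, per-replicate gamma-mixed Poisson counts
(NB dispersion 0.05) and a 3-fold amplitude in the matching tissue;
CBP/TF signal is unimodal at the summit; input is uniform. Expression
of adjacent genes follows enhancer activity (4-fold, lognormal noise);
motifs are planted as PWM-sampled instances in 60% of matching-class
cores and 10% elsewhere; conservation is Beta(2, 8) baseline plus
+0.15 over cores and +0.3 at planted motif bases, clamped to 1.

Defaults describe a 5-Mb genome with 200 ME + 200 DEE + 2600
non-differential candidates, 3 vs 2 replicates, ~600 k reads per
H3K27ac sample — sized so a full pipeline run takes well under a minute
while leaving > 100 expected counts per window. A 400-kb
`small_test_config` preserves the geometry for quick runs.

What the generator does **not** emulate: realistic base composition
beyond a global AT bias, mappability and GC bias, duplicate reads,
copy-number or chromatin-state heterogeneity, enhancer–promoter loops,
distance-dependent assignment ambiguity, and correlated motif grammars.
Passing tests therefore demonstrate that the statistics recover the
stated model when its assumptions hold — calibration, exactness, and
geometric pattern detection — not that biological data meet those
assumptions. Two model-level footnotes: abutting 1-kb windows let a
neighbor's flank fragments bleed ~9% of one flank into adjacent
windows (symmetric across tissues, hence neutral for calls, and
accounted for analytically in the generator's self-consistency test);
and PWM-sampled planted instances are detected in only ~50–65% of
cores at the default scan threshold, which is deliberate — enrichment
ranking must not depend on perfect-consensus planting.

## Numerical and degenerate-input policy

Zero-input enrichment is NaN at ε = 0; empty summit lists, empty
groups, zero-fragment samples and empty vectors raise; degenerate
proportion tables (pooled variance 0) yield NA and are skipped in
multiple testing; metapeak smoothing shrinks its window at profile
edges; score-distribution binning is 1e-3 bits; percentiles use linear
interpolation; ties everywhere break deterministically (leftmost /
lexicographic), so fixed seeds reproduce every output byte for byte.

## Known limitations

Dispersion estimation borrows nearly all its strength from the trend at
2–3 replicates; per-region dispersion differences are not resolvable at
that depth. The Wald test is asymptotic (no exact small-count test).
The DP p-value assumes independence between positions under the
background at the modeled order. The scanner holds sequences in memory,
which is appropriate for region cores and small genomes rather than
mammalian-scale whole-genome scans.
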