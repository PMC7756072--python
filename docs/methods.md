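# Methods

This note documents the models, defaults and design choices behind
crossregen, and what the synthetic benchmarks do and do not show.

## Synthetic data generator

The generator replaces the original external downloads and defines the
conditions every benchmark runs under.

**Count model.** Counts are negative binomial with variance
μ + φμ². Baseline means are lognormal (log-mean 5, log-sd 1.2 on the
natural scale, i.e. a median around 150 counts); dispersions follow a
log-linear trend in the mean (φ ≈ 0.08 at the reference mean, slope
−0.3) with lognormal gene scatter (sd 0.3) — the standard bulk RNA-seq
picture of decreasing dispersion with abundance. Library-size factors
are lognormal with sd 0.3 so TMM normalization has real work to do.

**Time course.** Ten timepoints (1, 4, 7, 14, 21, 30, 45, 60, 120,
160 days post injury), by default 3 injured and 2 sham fish per
timepoint and 4 healthy controls. The replicate counts are not stated
in the emulated design and are config-exposed defaults, not inferred
values. A fraction `frac_de` (default 0.25) of genes is assigned to one
of five archetype trajectories built from Gaussian bumps in log-time:
(1) down, trough 4–14 dpi; (2) down early, up late; (3) up early, down
late; (4) broad up around 21 dpi; (5) sharp up at 4–7 dpi returning to
baseline by 120 dpi — the qualitative shapes of the five response
groups the analysis is meant to separate. Planted amplitudes are
effect_size (default 2 log₂ units) with ±20% jitter. Sham fish carry
the same response scaled by `sham_scale` (0.3) and linearly damped to
zero by 30 dpi, which is what motivates the exponentially decaying
control weight downstream.

**Cohort.** `n_pairs` patients each contribute one tumor and one
normal sample sharing a per-patient, per-gene lognormal baseline effect
(sd 0.4 log₂ units) — the heterogeneity the paired design exists to
remove. The same planted gene indices as the time course are shifted in
tumors by ±effect_size, with the sign equal to the archetype's early
response sign; this gives the cross-condition comparison real signal to
recover. Each repressive miRNA (default one, 20 targets, slope −1,
noise sd 0.2) is shifted +2 log₂ units in tumors and its targets'
means are multiplied by 2^(slope·activity + noise) where activity is
the miRNA's per-sample log₂ deviation; the truth records the resulting
effective target shift (slope × up-shift) alongside the directly
planted fold changes.

**What the generator does not emulate.** Hidden batch structure (the
real pipeline used surrogate-variable correction; out of scope here),
age-dependent drift in the healthy controls, read-level artifacts, and
gene–gene correlation beyond the planted patient and miRNA couplings.
Passing benchmarks therefore demonstrate correctness of the statistical
machinery under a faithful NB sampling model, not robustness to batch
confounding or alignment artifacts.

## Normalization

TMM factors follow Robinson–Oshlack: reference = sample whose CPM upper
quartile is closest to the mean upper quartile; per sample, gene-wise
M-values (log₂ ratio vs reference) and A-values are doubly trimmed
(30% on M, 5% on A, both tails) over genes nonzero in both samples;
the factor is 2^(weighted mean of surviving M) with inverse asymptotic
binomial variance weights; factors are centered to geometric mean 1.
Centering is a documented choice (it only shifts all log-CPMs by a
constant). The expression filter (CPM ≥ 1 in ≥ 3 samples) uses raw
library sizes because filtering precedes normalization. log-CPM uses a
prior count of 0.5 scaled per million of effective library size, making
the transform finite and exactly invariant to global depth scaling.

## Differential expression

The DE engine is a moderated paired-difference test on log-CPM, not a
negative-binomial GLM: per pair the tumor−normal log₂-CPM difference
is formed and a one-sample moderated t is applied per gene. The
empirical-Bayes variance prior is estimated from the data by moment
matching on log s² (the scaled-F model behind moderated t), with the
prior variance following a lowess trend in mean log-CPM — this absorbs
the count-data mean–variance relationship and keeps null p-values
uniform, which a fixed prior degrees-of-freedom does not (a numeric
`prior_df` remains available). The claims this package makes are at the
threshold/rank level, and the benchmarks measure planted-truth
recovery, not parity with any particular NB implementation.

A tagwise NB dispersion fit (method-of-moments raw estimates shrunk
toward a lowess mean–dispersion trend with prior df 4) is provided for
the generator's calibration checks and as an NB-GLM extension point.

The time-course test treats the modeled control as a weighted sample:
sham replicates carry total weight w(t) and healthy replicates 1−w(t),
the control variance uses the weighted unbiased estimator, and the
effective control sample size is 1/Σwᵢ². As τ→0 the sham weight
underflows and the computation reduces exactly to injured vs healthy.

## Clustering

Fuzzy c-means with Euclidean distance on row-standardized trajectories.
Defaults: c = 5 (fixed by the emulated design), fuzzifier m = 1.25 —
on standardized data m = 2 drives memberships toward uniform, and 1.25
keeps the >70% core rule meaningful; k-means++-style seeding with 10
restarts keeping the best objective; a point coincident with a center
takes full membership (standard convention); ties in maximum membership
leave a gene unassigned (conservative, measure-zero). The objective
Σ u^m d² is non-increasing across iterations by construction and is
asserted in tests.

## Enrichment and the significance matrix

Over-representation is the one-sided Fisher exact test, computed as the
hypergeometric upper tail; one-sided is the ORA standard and the choice
is noted because two-sided is defensible. The ORA universe is the set
of genes surviving the expression filter of the relevant dataset. The
paired set statistic compares, per patient, a set's tumor−normal log
ratios against all genes' by Welch t, one-sided per direction, and
combines patients with Stouffer's method; this is a documented,
testable combiner rather than a reproduction of gage's internal
gamma-combination variants. Significance cutoffs are per source:
cluster ORA FDR < 0.1, cohort sets FDR < 0.01, miRNA target enrichment
nominal p < 0.01 (p, not FDR, deliberately). The significance matrix
encodes term×condition calls as up/down/ns; heatmap ordering uses
agglomerative clustering on Euclidean distance over the +1/−1/0
encoding with complete linkage (linkage unstated in the emulated
analysis; config-exposed).

## Term network

The sharing fraction uses the smaller set as denominator — this is the
convention under which the 98% de-duplication rule actually removes
subset-terms; Jaccard is selectable. De-duplication keep-priority is
smaller p, then larger set, then lexicographic name (the ordering is
otherwise unspecified). Both the 98% and the 40% rules are strict
inequalities. Layout is delegated to external tools; the export carries
node size (−log₁₀ p), cluster attachment weights and edge sharing
fractions.

## Ortholog mapping and stage split

Set-level tests use `expand` mode (a gene with several orthologs
contributes all of them); fold-change heatmaps use `first` mode, where
"first" is the ortholog-map file row order — the documented determinism
source. The stage-split comparison scales −log₁₀ FDR to [0,1] per
stage (the per-stage reading of the min–max scaling; pooled scaling
would only change both axes monotonically) and reports the Pearson r
between early and late scaled profiles.

## miRNA screen

Correlation FDR is computed globally within each direction split
(miR-up/mRNA-down vs miR-down/mRNA-up) — more conservative than
per-miRNA adjustment; switchable. "Combining" miRNAs is implemented as
connected components over significant-overlap edges (single-linkage
transitivity), with the hypergeometric universe being the mRNAs that
entered the correlation screen for that split. The top-15 rule is
applied after merging, counting groups as entities; per-member target
counts are retained for reporting.

## Numerical choices and degenerate inputs

Zero-variance expression vectors are skipped with a log entry in the
correlation screen; constant trajectories are excluded from z-scoring
with a warning; a timepoint with no sham samples errors unless the
healthy fallback is configured; IQR ties in ID de-duplication break by
total count then lexicographic ID; all-zero p-value vectors and empty
call sets propagate as empty results, not errors. All randomness
derives from a single integer seed through named, process-stable
substreams; reruns are byte-identical, which the pipeline manifest
(SHA-256 per output) makes checkable.

## Benchmark problem sizes

The recovery and calibration benchmarks run at 1500–2000 genes,
10–15 pairs and 20 seeds; the full-pipeline reproducibility check runs
at 600–800 genes. These sizes give stable averages for rate estimates
while keeping the suite quick to run; all are config-exposed, and the
same code paths run unchanged at larger sizes.

## Known limitations

The DE engine's log-CPM approximation loses accuracy for very low
counts (< ~5) where the NB likelihood matters most; the modeled
control's τ is fixed, not fitted; GO graph topology (parent–child
propagation) is not modeled, so enrichment treats terms as flat sets;
cross-species comparison is at the term level only — no joint
normalization across species is attempted, and miRNA IDs are never
mapped across species.
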