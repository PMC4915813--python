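# Methods

`chromregime` implements the computational core of a genome-wide chromatin
analysis: a binomial-mixture model of ChIP-seq enrichment over a control,
summit-centred signal matrices with k-means chromatin-regime clustering,
peak-set overlap quantification, promoter-window target-gene assignment,
and rank-based comparison of promoter signal across differential-expression
classes. Everything runs on plain-text inputs (BED6 read tags, narrowPeak
peaks, TSV tables) and is exercised end-to-end on synthetic data with known
ground truth.

## Enrichment model

For region *i* with ChIP count s_i and control count r_i we condition on
the total n_i = s_i + r_i and model the ChIP fraction as a two-component
binomial mixture,

    s_i | n_i ~ pi_bg · Binom(n_i, θ_bg) + (1 − pi_bg) · Binom(n_i, θ_sig),

where the background component captures reads split between ChIP and
control at the library-size ratio and the signal component captures genuine
enrichment. Conditioning on totals is the simplest model consistent with
paired per-region counts and is exactly the structure the enrichment
statistic below regularizes.

**Fitting.** EM with identical (s, r) rows aggregated (runtime scales with
distinct count pairs, not regions). The first initialization places the two
fractions at the 0.4/0.6 quantiles of the observed s/(s+r); the remaining
`restarts − 1` (default 5 total) are random but derived from the given
seed, so fits are deterministic. Convergence when successive
log-likelihoods differ by less than `tol` (default 1e−8, cap 1000
iterations); the best converged likelihood wins and components are
relabelled so θ_bg ≤ θ_sig. The log-likelihood trace is retained and tested
for monotonicity; on tiny instances the converged likelihood is checked
against a dense 0.01-step grid search over (θ_bg, θ_sig, π). Fits with a
single region or indistinguishable components complete but carry a
`degenerate` flag and a warning.

**Pseudo counts and statistic.** Pseudo counts are derived from the
background component: α_s = c·θ_bg and α_r = c·(1−θ_bg) with mass c = 1 by
default. This is the unique first-order rule for which a region sitting at
the background ChIP:control ratio scores zero — including the empty region
s = r = 0 — while low counts are shrunk towards zero. The raw regularized
log enrichment is

    e*_i = ln( (s_i + α_s) / (r_i + α_r) · α_r / α_s ),

strictly increasing in s, decreasing in r, and finite everywhere.

**Normalization.** ln⟨f⟩ is the posterior-weighted mean of e* over the
signal component (soft assignment); the normalized score is
e_i = e*_i / ln⟨f⟩, so the signal component's weighted mean of e is 1 by
construction and background regions sit near 0. Two documented switches
exist: `average="fold"` takes the log of the weighted mean fold change
instead of the mean of logs, and `mode="multiply"` multiplies rather than
divides by ln⟨f⟩. Division with mean-of-logs is the default because
"normalizing by" an average log enrichment most naturally means dividing by
it, and it gives the interpretable 0/1 fixed points above. ln⟨f⟩ ≤ 0 raises
an error suggesting swapped treatment/control.

## Signal matrices and regime clustering

Read tags carry only a 5′ position and strand. ChIP-track 5′ ends are
shifted 100 bp downstream (plus-strand +100, minus-strand −100, clamped at
0) to centre the fragment estimate; accessibility tracks are left
unshifted via a per-track `shift` setting. Counts are taken in
non-overlapping 51-bp bins spanning ±5100 bp around each peak summit (200
bins); a tag lands in the unique bin containing its shifted 5′ end, tags
outside the window are ignored, windows overhanging the chromosome start
are kept and count whatever falls in the valid part, and overlapping
windows count independently.

Each track's matrix is clipped at the 99.9% quantile of all its entries
(linear interpolation between order statistics — the numpy default; the
quantile type is fixed and documented because different conventions move
the clip value) and divided by that value, mapping the matrix into [0, 1]
with maximum exactly 1. An all-zero matrix is an error rather than a NaN
factory. Clip-normalization is idempotent to ~1e−12.

Tracks are concatenated horizontally (configurable exclusion set — by
default nothing is excluded; a pipeline config typically excludes the track
whose peaks anchor the windows) and clustered with k-means, k = 2, k-means++
initialization, 10 restarts, fixed seed. Cluster ids are canonicalized by
descending cluster size; peaks are ordered for display by (cluster
ascending, peak score descending) with a stable sort. Per-cluster,
per-track mean profiles summarize the regimes; an empty cluster produces a
zero profile and a warning.

## Interval analysis

Intersection is ≥1-bp overlap under 0-based half-open semantics, computed
by a per-chromosome sorted sweep and verified against an all-pairs brute
force. Overlap summaries report both directions (share of A peaks hitting
B, and vice versa) as counts and percentages.

TSS windows are symmetric and inclusive: ±1500 bp around a TSS becomes the
half-open interval [tss − 1500, tss + 1501), clamped at 0; strand does not
alter the geometry. A gene is a target if any of its TSS windows intersects
any peak, so adding peaks can only add targets. For each gene a
representative promoter is the TSS with the highest designated-track
enrichment (ties: smallest genomic coordinate). Promoter counts are 5′-end
counts of pre-shifted ChIP and control tags per window, feeding the
enrichment model.

## Group statistics

Per track, six one-sided Wilcoxon rank-sum tests: up vs unchanged, down vs
unchanged, down vs up, each in both directions, mirroring a boxplot with
significance bars above (higher) and below (lower). The test is exact by
enumeration when the combined sample size is ≤ 12 with no ties, otherwise
the normal approximation with tie and continuity correction; at n = 6 + 6
the approximation is within 0.008 of exact (the sharp bound over all U
values). Stars are boundary-inclusive: p ≤ 0.01 one, p ≤ 0.001 two,
p ≤ 0.0001 three. No multiple-testing correction is applied by default —
the raw per-comparison p-values are the reported quantity — and group
sizes below 3 trigger a warning.

## Synthetic data: what it emulates, and what it does not

All generators flow from one master seed through named sub-streams
(counts, placement, labels, scores, DE), so each stage is individually
reproducible and same-seed runs are byte-identical.

* `simulate_counts` draws, per region, n_i ~ Poisson(depth_mean = 20),
  a component with background weight pi_bg = 0.9, and
  s_i ~ Binom(n_i, θ) with θ_bg = 0.5 / θ_sig = 0.8; defaults give the
  reference recovery conditions (10,000 regions). Because the generator is
  the fitted model, parameter recovery isolates estimator correctness.
* `simulate_regime_dataset` alternates 500 + 500 peaks between two regimes
  along one synthetic chromosome, spaced so counting windows never
  overlap. Two default tracks are regime-exclusive ("repressive_mark"
  intense on regime A, "active_mark" on regime B, 200 vs 10 expected reads
  per peak); read 5′ offsets are uniform on ±1000 bp with a fair strand —
  a deliberately simple placement model, since only binned counts matter
  downstream. Peak scores are Gamma(shape 2, scale 20), a right-skewed
  distribution resembling peak-caller score lists.
* `simulate_de_labels` assigns groups with proportions up 0.15 / down
  0.15 / unchanged 0.70 and draws per-track promoter counts whose ChIP
  fraction is shifted per group on the logit scale (defaults:
  active-mark signal highest on down-regulated genes, repressive-mark
  highest on up-regulated ones), so configured orderings hold in
  expectation and the directional tests have a known answer.

Not emulated: fragment-length and GC structure, genome sequence, mappability,
copy-number variation, inter-replicate variability, and spatial
autocorrelation of background. Passing tests therefore demonstrate that the
estimators and pipeline recover the structure they assume, not that real
libraries satisfy those assumptions.

## Numerical choices and problem sizes

θ is clipped to [1e−12, 1 − 1e−12] inside EM; likelihoods include the
binomial coefficient so they are comparable across parameterizations;
EM restart ties break to the first-best likelihood. Quantiles use linear
interpolation. Stable sorts everywhere a tie rule is stated. The bundled
test-suite and demo problem sizes — 10,000 mixture regions, 1,000 peaks ×
200 bins × 3 tracks, ~650 genes — run the full pipeline in seconds while
leaving Monte-Carlo error well inside the recovery tolerances (±0.02 on
θ and π, ARI ≥ 0.95, label accuracy ≥ 0.95).

## Known limitations

Two mixture components only (no multi-state enrichment calling, no FDR
control); no BAM/BigWig I/O (BED/TSV only, by design — a BAM adapter would
be an optional extra); nearest-gene assignment and minimum-overlap-fraction
rules are out of scope; the k-means regime count k is a parameter, not
selected automatically; plotting is intentionally absent — all outputs are
numeric tables ready for any heatmap/boxplot frontend.
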