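# chromregime

Tools for the computational half of a chromatin-profiling study: given
ChIP-seq read tags, peak calls with summits, a TSS annotation and
differential-expression labels, `chromregime` quantifies per-region
enrichment over a control with a binomial mixture model, builds
summit-centred signal heatmatrix inputs, partitions peaks into chromatin
regimes by k-means, measures peak-set overlaps, assigns promoter-window
target genes, and compares promoter signal between up-, down- and
unregulated gene classes with directional rank-sum tests. It is aimed at
computational biologists who already have alignments, peaks and DE calls
and want the downstream integration to be reproducible, seeded and
testable — every stage can also run on bundled synthetic data with known
ground truth.

## The model at the core

For region *i*, let s_i be the ChIP read count and r_i the control count.
Conditioning on n_i = s_i + r_i, the ChIP fraction follows a two-component
binomial mixture

    s_i | n_i ~ π_bg · Binom(n_i, θ_bg) + (1 − π_bg) · Binom(n_i, θ_sig),

fit by seeded, restarted EM. Pseudo counts α_s = c·θ_bg, α_r = c·(1−θ_bg)
derived from the background component regularize the log enrichment

    e*_i = ln( (s_i + α_s) / (r_i + α_r) · α_r / α_s ),

which is exactly 0 for a region at the background ChIP:control ratio
(including empty regions) and shrinks low-count regions towards 0.
Dividing by ln⟨f⟩, the posterior-weighted mean of e* over the signal
component, gives the normalized enrichment e_i = e*_i / ln⟨f⟩: background
≈ 0, typical signal ≈ 1.

Downstream, read 5′ ends (shifted 100 bp downstream for ChIP tracks,
unshifted for accessibility tracks) are counted in 51-bp bins over
±5100 bp around peak summits, clipped at the 99.9% count quantile and
divided by it, concatenated across tracks, and clustered with k-means
(k = 2). Target genes are genes whose ±1500 bp TSS window intersects a
peak; group differences use one-sided Wilcoxon rank-sum tests with stars
at p ≤ 0.01 / 0.001 / 0.0001.

## Worked example

Simulate 10,000 regions from the mixture (θ_bg = 0.5, θ_sig = 0.8,
π_bg = 0.9, mean depth 20) and fit it back:

```sh
python -c "
from chromregime import SimConfig, simulate_counts, write_table
counts, _ = simulate_counts(SimConfig(seed=1))
write_table(counts, 'counts.tsv')"
chromregime enrich --counts counts.tsv --seed 1 --out scores.tsv
```

prints

```
theta_bg=0.5018 theta_sig=0.8025 pi_bg=0.9054 ln_f=1.4007
```

— the fitted background fraction (0.5018 vs true 0.5), signal fraction
(0.8025 vs 0.8), background weight (0.9054 vs 0.9) and the signal
component's average log enrichment. `scores.tsv` holds per-region e*, the
normalized e and the posterior signal probability:

```
region_id	e_star	e	posterior
region_0	-0.827809853898	-0.590985465806	1.64983947813e-05
region_1	-0.23882433607	-0.170500158742	4.33698116699e-05
```

The one-command demo generates a complete synthetic study (mixture counts,
two-regime peaks with three read-tag tracks, a TSS annotation, DE labels
with group-shifted promoter counts), runs every stage, and reports how well
the ground truth is recovered:

```sh
chromregime demo --seed 1 --out demo_run
cat demo_run/recovery_report.json
```

```json
{
  "clustering_ari": 1.0,
  "label_accuracy": 0.9586,
  "n_target_genes_expected": 500,
  "n_target_genes_found": 500,
  "pi_bg_hat": 0.90541272537,
  "stars_down_gt_unchanged_active": 3,
  "stars_up_gt_down_repressive": 3,
  "theta_bg_hat": 0.501826884076,
  "theta_sig_hat": 0.802467676715
}
```

Clustering recovered the two simulated regimes perfectly (adjusted Rand
index 1.0), 95.9% of regions were labelled correctly at posterior 0.5, all
500 genes placed at peak summits were called targets, and the simulated
group effects (active-mark signal highest in down-regulated genes,
repressive-mark in up-regulated) reached three significance stars in the
expected directions. Rerunning with the same seed is byte-identical; see
`demo_run/manifest.json` for per-file checksums.

Other subcommands (`simulate`, `matrix`, `cluster`, `overlap`, `targets`,
`compare`, `run`) expose the individual stages; `chromregime run --config
config.yaml --out dir` drives the whole pipeline from one YAML file.

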