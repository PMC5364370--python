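# chromcascade

Analysis of signal-induced histone-modification cascades at transcription
start sites and remote regulatory elements.

Mitogenic stimulation of fibroblasts activates ERK signalling and the TCF
family of SRF cofactors (Elk-1 and its paralogs), driving rapid changes
in a set of combinatorial histone marks — H3K9acS10ph, H4K16ac, H3K27ac,
H3K9acK14ac, H3K4me3 — at thousands of promoters.  `chromcascade`
implements the complete quantitative pipeline for this kind of study, for
computational biologists analysing multi-mark, multi-genotype,
time-resolved ChIP-seq alongside RNA-seq:

* **Invariant-region scaling** between ChIP samples, two ways: factors
  anchored on RNA-defined invariant genes, or a trimmed maximum-likelihood
  Gaussian fit to per-region log2 differences (factor `2^(−μ_diff)`),
  cross-validated against each other.
* **Negative-binomial differential calling** at TSS (−2 kb..+1 kb) and
  DNase I HS (±2 kb) windows: conditional exact test on pooled replicate
  counts with method-of-moments dispersions shrunk to a fitted
  `α(μ) = a₀ + a₁/μ` trend; >20% change at p < 0.05 for TSS windows,
  ≥2-fold at BH-adjusted p < 0.01 for DNase windows.
* **The Distance Index** quantifying the nested mark hierarchy: for a
  leading mark with fold changes `x` and comparison mark `y`,
  `DI = 100·Σ(x_i − y_i)/n` over the regions with `x_i > 1`, plus
  single-linkage mark dendrograms with multiscale-bootstrap AU support.
* **Genotype-dependence estimation** from fold-change asymmetry between
  backgrounds (wild type vs TCF-knockout and Elk-1 variant rescues),
  including the restoration classification across Elk-1 mutants.
* **Metaprofiles** (strand-oriented, 51-bp smoothed, ±150 bp core masked)
  and difference profiles.
* **Log-log regression** of transcriptional change (intronic-read fold
  change, ORF fallback) on mark changes, with skewness screening,
  stepwise AIC selection, and Cook's-distance diagnostics.
* A **ground-truthed synthetic-data generator** emulating the study
  design (5 marks × 5 genetic backgrounds × resting + 5/15/30 min
  stimulation × 2 replicates) for end-to-end validation of every stage.

See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

Run the full analysis on the default synthetic study (2,000 TSS windows,
1,000 remote sites, seed 1):

```python
from chromcascade import PipelineConfig, SimulationConfig, run_full_analysis

summary = run_full_analysis(PipelineConfig(simulation=SimulationConfig(seed=1)))
h = summary["hierarchy"]["di_row_leading"]
print({k: round(v, 1) for k, v in h.items()})
print("changed TSS regions:", summary["differential"]["n_tss_changed"])
print("TCF-dependent fraction:", round(summary["dependence"]["dependent_fraction"], 2))
print("restored by Elk-1:", round(summary["dependence"]["restored_fraction"], 2))
print("adjusted R^2 (5-mark model):", round(summary["regression"]["adj_r2_full"], 2))
```

prints

```
{'H4K16ac': 15.2, 'H3K27ac': 33.6, 'H3K9acK14ac': 40.5, 'H3K4me3': 47.4}
changed TSS regions: 452
TCF-dependent fraction: 0.58
restored by Elk-1: 0.67
adjusted R^2 (5-mark model): 0.38
```

Reading the output: with H3K9acS10ph as the leading mark, the other marks
are less induced by on average 15–47 percentage points of fold change, in
the nested order H4K16ac < H3K27ac < H3K9acK14ac < H3K4me3 — the
induction hierarchy.  Over half of the changed regions measurably lose
their induction in cells lacking all three TCFs (a lower bound: the
split-replicate dependence design trades power for a calibrated null —
see `docs/methods.md`); re-expressing wild-type Elk-1 restores roughly
two thirds of those.  The five marks' changes jointly explain ~40% of the
variance in transcriptional induction of the associated genes.

The same pipeline is scriptable from the shell:

```bash
chromcascade simulate --seed 1 --out sim/
chromcascade run-all --seed 1 --nboot 1000 --out results/
chromcascade annotate --tss sim/tss.bed --srf sim/srf_peaks.bed \
    --hic sim/hic_links.tsv --out targets.tsv
```

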