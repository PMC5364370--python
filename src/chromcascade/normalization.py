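"""Depth normalization and invariant-region scaling factors.

Two independent routes anchor ChIP samples to a reference sample:

* **invariant-genes** (method 1): factors equalize the summed signal over
  the TSS windows of a set of actively transcribed genes whose RNA output
  is invariant across all conditions;
* **gaussian-fit** (method 2): per-region log2 signal differences versus
  the reference are modeled as a Gaussian (maximum likelihood); regions
  within 1σ of the fitted mean difference define the invariant set and the
  factor is ``2**(-mu_diff)``.

Both are gauge-fixed: the reference sample's factor is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix

TARGET_DEPTH = 30_000_000  # reads; the common depth all samples are scaled to
PSEUDOCOUNT = 0.5


@dataclass
class ScalingFactorSet:
    """Per-sample multiplicative factors relative to a reference sample."""

    reference: str
    factors: pd.Series  # sample id -> factor, factors[reference] == 1
    method: str  # "invariant-genes" | "gaussian-fit"
    mu_diff: pd.Series | None = None
    sigma_diff: pd.Series | None = None
    invariant_regions: dict[str, pd.Index] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.factors[self.reference], 1.0):
            raise ValueError("reference factor must be 1")
        if (self.factors <= 0).any():
            raise ValueError("all factors must be positive")


def depth_normalize(counts: CountMatrix, aligned_totals: pd.Series) -> CountMatrix:
    """Scale each sample to a common total of 30 million aligned reads."""
    totals = aligned_totals.reindex(counts.counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive aligned-read total")
    return CountMatrix(counts.counts * (TARGET_DEPTH / totals), counts.samples.copy())


def select_invariant_genes(
    intronic: CountMatrix,
    de_test,
    min_intronic: float = 6.0,
    sd_frac: float = 0.15,
    p_threshold: float = 0.05,
    dispersion: float = 0.02,
) -> pd.Index:
    """Genes transcribed invariantly across all conditions.

    Criteria: (i) mean intronic reads >= ``min_intronic``; (ii) no condition
    differs significantly from the first (reference) condition, per
    ``de_test(k_a, k_b, size_a, size_b, alpha)`` on replicate-pooled
    counts — "not significantly different across all conditions" is one
    compound claim per gene, so the per-comparison level is Bonferroni-
    divided by the number of comparisons; (iii) the standard deviation of
    per-condition means is below ``sd_frac`` of the grand mean.
    """
    meta = intronic.samples
    cond_keys = meta[["background", "condition", "time"]].astype(str).agg("|".join, axis=1)
    conditions = list(dict.fromkeys(cond_keys))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    groups = {c: meta.index[cond_keys == c] for c in conditions}
    cond_means = pd.DataFrame(
        {c: intronic.counts[cols].mean(axis=1) for c, cols in groups.items()}
    )
    expressed = cond_means.mean(axis=1) >= min_intronic

    ref_cols = groups[conditions[0]]
    k_ref = intronic.counts[ref_cols].sum(axis=1).to_numpy()
    stable = np.ones(len(intronic.counts), dtype=bool)
    per_test = p_threshold / (len(conditions) - 1)
    for c in conditions[1:]:
        cols = groups[c]
        k = intronic.counts[cols].sum(axis=1).to_numpy()
        p = de_test(k_ref, k, float(len(ref_cols)), float(len(cols)), dispersion)
        stable &= np.asarray(p) >= per_test

    grand = cond_means.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_ok = (cond_means.std(axis=1, ddof=1) / grand).fillna(np.inf) < sd_frac

    keep = expressed & stable & cv_ok.to_numpy()
    return intronic.counts.index[keep]


def scaling_method1(
    tss_counts: CountMatrix,
    invariant_genes: pd.Index,
    reference: str,
) -> ScalingFactorSet:
    """Factors equalizing the invariant-gene TSS-window totals.

    factor(sample) = sum over invariant windows in the reference divided by
    the same sum in the sample, so applying the factors makes every
    sample's invariant-set total equal the reference's.
    """
    rows = tss_counts.counts.index.intersection(invariant_genes)
    if len(rows) == 0:
        raise ValueError("invariant gene set is empty on this count table")
    sums = tss_counts.counts.loc[rows].sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"zero invariant-set signal in sample {bad!r}")
    factors = sums[reference] / sums
    return ScalingFactorSet(reference, factors, "invariant-genes",
                            invariant_regions={s: rows for s in sums.index})


def fit_invariant_gaussian(
    deltas: np.ndarray | pd.Series,
    iterate: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, float, np.ndarray]:
    """Single-Gaussian ML fit to per-region log2 differences vs reference.

    Maximum likelihood for a single Gaussian is the sample mean/SD.  In the
    default iterative mode the fit starts from the median and the
    MAD-derived scale (so a genuinely changing minority cannot drag the
    starting point), then the set is trimmed to within 1σ of μ and refit
    until μ moves by less than ``tol``, which pulls the fit onto the
    invariant bulk.  Returns ``(mu_diff, sigma_diff, invariant_mask)``
    over the input regions.
    """
    x = np.asarray(deltas, dtype=float)
    if len(x) == 0:
        raise ValueError("no regions to fit")
    mu, sigma = float(np.mean(x)), float(np.std(x))
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        return mu, 0.0, np.ones(len(x), dtype=bool)
    if iterate:
        mu = float(np.median(x))
        mad_sigma = 1.4826 * float(np.median(np.abs(x - mu)))
        if mad_sigma > 0:
            sigma = mad_sigma
        for _ in range(max_iter):
            keep = np.abs(x - mu) <= sigma
            if keep.sum() < 2:
                break
            new_mu, new_sigma = float(np.mean(x[keep])), float(np.std(x[keep]))
            done = abs(new_mu - mu) < tol
            mu, sigma = new_mu, new_sigma
            if done or sigma == 0.0:
                break
    invariant = np.abs(x - mu) <= sigma if sigma > 0 else np.ones(len(x), bool)
    return mu, sigma, invariant


def scaling_method2(
    tss_counts: CountMatrix,
    reference: str,
    region_subset: pd.Index | None = None,
    iterate: bool = True,
) -> ScalingFactorSet:
    """Gaussian-fit factors: ``2**(-mu_diff)`` per sample vs reference.

    δ is computed on log2(count + 0.5) differences.  ``region_subset``
    restricts the fit, e.g. to DNase I HS windows for marks whose TSS
    signal is too weak to anchor the fit.
    """
    counts = tss_counts.counts
    if region_subset is not None:
        counts = counts.loc[counts.index.intersection(region_subset)]
    if len(counts) < 100:
        raise ValueError("need at least 100 regions for the Gaussian fit")
    log_ref = np.log2(counts[reference] + PSEUDOCOUNT)
    mus, sigmas, factors, inv_sets = {}, {}, {}, {}
    for sample in counts.columns:
        delta = np.log2(counts[sample] + PSEUDOCOUNT) - log_ref
        mu, sigma, inv = fit_invariant_gaussian(delta.to_numpy(), iterate=iterate)
        mus[sample], sigmas[sample] = mu, sigma
        factors[sample] = float(2.0 ** (-mu))
        inv_sets[sample] = counts.index[inv]
    factors[reference] = 1.0  # exact gauge despite pseudocount arithmetic
    return ScalingFactorSet(
        reference, pd.Series(factors), "gaussian-fit",
        mu_diff=pd.Series(mus), sigma_diff=pd.Series(sigmas),
        invariant_regions=inv_sets,
    )


def compare_scaling_methods(
    normalized_m1: CountMatrix,
    normalized_m2: CountMatrix,
) -> pd.DataFrame:
    """Per-sample OLS slope and Spearman correlation between the two
    normalizations of the same counts (identical methods give slope 1)."""
    a, b = normalized_m1.counts, normalized_m2.counts
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("normalized tables must share regions and samples")
    rows = []
    for sample in a.columns:
        x, y = a[sample].to_numpy(), b[sample].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        rho = stats.spearmanr(x, y).statistic
        rows.append((sample, slope, intercept, rho))
    return pd.DataFrame(rows, columns=["sample", "slope", "intercept", "spearman_r"]
                        ).set_index("sample")
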