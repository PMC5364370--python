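"""Negative-binomial differential calling at TSS and DNase HS windows.

The engine is the classic count-based exact test: replicate counts are
pooled per condition, the total is conditioned on, and the two-sided
p-value sums the probabilities of all splits no more likely than the
observed one under NB sampling (variance = mu + alpha*mu^2) proportioned
by size factors.  Dispersion is estimated per region by method of moments
from replicate variance and shrunk conservatively to the larger of the
per-region value and a fitted alpha(mu) = a0 + a1/mu trend.

Calling rules differ by window class: TSS regions use >20% change with raw
p < 0.05 above a per-mark 25th-percentile count floor; DNase HS windows
use at least 2-fold change with Benjamini-Hochberg adjusted p < 0.01 above
a floor of five times the pooled 25th percentile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

_REL_TOL = 1e-8  # splits within this relative probability of the observed
                 # one count as "no more likely" (guards float ties)

_CHUNK = 2_000_000  # outcome-grid elements processed per batch


def nb_exact_test(k_a, k_b, size_a=1.0, size_b=1.0, alpha=0.0):
    """Two-sided conditional exact p-value for one count pair.

    ``size_a``/``size_b`` are the summed size factors of the pooled
    replicates.  ``alpha=0`` reduces to the exact binomial split of the
    total.  Scalars in, scalar out; see :func:`nb_exact_test_many` for the
    vectorized form.
    """
    p = nb_exact_test_many(
        np.atleast_1d(k_a), np.atleast_1d(k_b),
        np.atleast_1d(float(size_a)), np.atleast_1d(float(size_b)),
        np.atleast_1d(float(alpha)),
    )
    return float(p[0])


def _conditional_logpmf(a, s_tot, mu_a, mu_b, alpha):
    """log P(split = (a, S-a)) up to the conditioning constant."""
    if alpha <= 0:
        q = mu_a / (mu_a + mu_b)
        return stats.binom.logpmf(a, s_tot, q)
    r = 1.0 / alpha
    return (stats.nbinom.logpmf(a, r, r / (r + mu_a))
            + stats.nbinom.logpmf(s_tot - a, r, r / (r + mu_b)))


def nb_exact_test_many(k_a, k_b, size_a, size_b, alpha):
    """Vectorized exact test over regions (one p-value per row)."""
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    if (k_a < 0).any() or (k_b < 0).any():
        raise ValueError("counts must be nonnegative")
    size_a = np.broadcast_to(np.asarray(size_a, float), k_a.shape)
    size_b = np.broadcast_to(np.asarray(size_b, float), k_a.shape)
    alpha = np.broadcast_to(np.asarray(alpha, float), k_a.shape)
    if (alpha < 0).any():
        raise ValueError("dispersion must be >= 0")

    total = k_a + k_b
    pvals = np.ones(len(k_a))
    order = np.argsort(total, kind="stable")
    lengths = total[order] + 1
    bounds = np.cumsum(lengths)
    start = 0
    while start < len(order):
        # grow the batch until the concatenated outcome grid hits _CHUNK
        base = bounds[start - 1] if start else 0
        stop = int(np.searchsorted(bounds, base + _CHUNK, side="left")) + 1
        stop = min(stop, len(order))
        idx = order[start:stop]
        pvals[idx] = _exact_batch(k_a[idx], k_b[idx], size_a[idx], size_b[idx], alpha[idx])
        start = stop
    return pvals


def _exact_batch(k_a, k_b, size_a, size_b, alpha):
    s_tot = k_a + k_b
    lens = s_tot + 1
    offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])
    n_el = int(lens.sum())
    seg = np.repeat(np.arange(len(k_a)), lens)
    a = (np.arange(n_el) - offsets[seg]).astype(float)
    b = s_tot[seg] - a

    # log-probability of each split up to per-segment constants, which
    # cancel in the segment-normalized sums below; empty totals (S=0)
    # have the single trivial outcome and p = 1
    mu = np.where(s_tot > 0, s_tot, 1) / (size_a + size_b)
    mu_a, mu_b = mu * size_a, mu * size_b
    lp = np.empty(n_el)
    pois = alpha <= 0
    el_pois = pois[seg]
    if el_pois.any():
        # conditional on the total, the Poisson split is binomial
        log_odds = np.log(mu_a / mu_b)[seg][el_pois]
        ap, bp = a[el_pois], b[el_pois]
        lp[el_pois] = (-gammaln(ap + 1.0) - gammaln(bp + 1.0) + ap * log_odds)
    el_nb = ~el_pois
    if el_nb.any():
        with np.errstate(divide="ignore"):
            r = np.where(pois, 1.0, 1.0 / np.where(pois, 1.0, alpha))
            la = np.log(mu_a / (r + mu_a))
            lb = np.log(mu_b / (r + mu_b))
        an, bn = a[el_nb], b[el_nb]
        rn = r[seg][el_nb]
        lp[el_nb] = (gammaln(an + rn) - gammaln(an + 1.0) + an * la[seg][el_nb]
                     + gammaln(bn + rn) - gammaln(bn + 1.0) + bn * lb[seg][el_nb])

    seg_max = np.maximum.reduceat(lp, offsets)
    probs = np.exp(lp - seg_max[seg])
    denom = np.add.reduceat(probs, offsets)
    p_obs = probs[offsets + k_a]
    mask = probs <= p_obs[seg] * (1.0 + _REL_TOL)
    numer = np.add.reduceat(np.where(mask, probs, 0.0), offsets)
    return np.minimum(numer / denom, 1.0)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series | None = None,
) -> tuple[pd.Series, dict]:
    """Per-region NB dispersion with a conservative trend floor.

    Method of moments on the common (size-factor-corrected) scale: the
    replicate variance in excess of the counting-noise expectation, over
    the squared mean.  A two-parameter trend ``alpha(mu) = a0 + a1/mu`` is
    fitted across regions and the final value is the larger of the
    per-region estimate and the trend (the conservative choice of the
    first-generation count-based callers).  With no replicated group the
    fallback pools every sample into one group, confounding condition with
    noise (documented: a deliberately conservative blind estimate).
    """
    if size_factors is None:
        size_factors = pd.Series(1.0, index=counts.columns)
    size_factors = size_factors.reindex(counts.columns)
    q = counts / size_factors

    labels = pd.Series(groups).reindex(counts.columns)
    replicated = [g for g, cols in labels.groupby(labels).groups.items() if len(cols) >= 2]
    if not replicated:
        labels = pd.Series("pooled", index=counts.columns)
        replicated = ["pooled"]

    base_mean = q.mean(axis=1)
    var_num = pd.Series(0.0, index=counts.index)
    df_sum = 0
    for g in replicated:
        cols = labels.index[labels == g]
        var_num += q[cols].var(axis=1, ddof=1) * (len(cols) - 1)
        df_sum += len(cols) - 1
    w = var_num / df_sum
    xi = base_mean * float((1.0 / size_factors).mean())

    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (w - xi) / base_mean**2
    filtered = ~np.isfinite(raw) | (base_mean <= 0)
    raw_clamped = raw.clip(lower=0.0)

    ok = ~filtered
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok].to_numpy(), rcond=None)
    a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))

    trend = a0 + a1 / base_mean.replace(0, np.nan)
    final = np.maximum(raw_clamped, trend)
    final[filtered] = np.nan
    info = {"a0": a0, "a1": a1, "raw": raw_clamped, "trend": trend,
            "filtered": filtered, "base_mean": base_mean}
    return final, info


# ---------------------------------------------------------------------------
# Thresholding and calling
# ---------------------------------------------------------------------------

def select_count_threshold(pooled_counts, mode: str = "tss") -> float:
    """Minimum-read floor: the 25th percentile of the pooled count
    distribution (TSS mode), or five times it (DNase mode)."""
    pooled = np.asarray(pooled_counts, dtype=float)
    if pooled.size == 0:
        raise ValueError("empty count distribution")
    q25 = float(np.percentile(pooled, 25))
    if mode == "tss":
        return q25
    if mode == "dnase":
        return 5.0 * q25
    raise ValueError(f"unknown mode {mode!r}")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    counts: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
    size_factors: pd.Series,
    alphas: pd.Series,
    mark: str = "",
    min_count: float = 0.0,
) -> pd.DataFrame:
    """Per-region differential result between two sample groups.

    Counts are pooled within each group; the size factors entering the
    test are summed likewise (scaling-factor composition happens upstream,
    so a global rescaling of every sample cancels).  The per-sample
    dispersion is rescaled to the pooled counts — a sum of replicate NB
    draws has dispersion ``alpha * sum(s^2) / sum(s)^2``, so testing the
    pooled pair at the raw per-sample alpha would be systematically
    conservative.  Regions whose pooled normalized signal falls below
    ``min_count`` are flagged and not tested.
    """
    k_a = counts[cols_a].sum(axis=1)
    k_b = counts[cols_b].sum(axis=1)
    sf = size_factors.reindex(counts.columns)
    s_a, s_b = float(sf[cols_a].sum()), float(sf[cols_b].sum())
    mean_a = (k_a / s_a).to_numpy()
    mean_b = (k_b / s_b).to_numpy()

    pooled_norm = (k_a + k_b) / (s_a + s_b)
    passed = (pooled_norm >= min_count).to_numpy() & ((k_a + k_b) > 0).to_numpy()
    a = alphas.reindex(counts.index).to_numpy(dtype=float)
    a = np.where(np.isfinite(a), a, 0.0)
    pool_shrink = float(np.mean([
        (sf[cols_a] ** 2).sum() / s_a**2,
        (sf[cols_b] ** 2).sum() / s_b**2,
    ]))
    a = a * pool_shrink

    p = np.full(len(counts), np.nan)
    if passed.any():
        p[passed] = nb_exact_test_many(
            k_a.to_numpy()[passed], k_b.to_numpy()[passed],
            np.full(passed.sum(), s_a), np.full(passed.sum(), s_b), a[passed],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(mean_a > 0, mean_b / mean_a, np.nan)
    return pd.DataFrame(
        {
            "mark": mark,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": fold,
            "p_value": p,
            "passed_count_filter": passed,
        },
        index=counts.index,
    )


def call_changed_regions(results: pd.DataFrame, mode: str = "tss") -> pd.DataFrame:
    """Apply the significance rules and return the table with ``adjusted_p``
    and ``significant`` columns added.

    TSS mode: change of more than 20% in either direction with raw
    p < 0.05.  DNase mode: at least 2-fold change with BH-adjusted
    p < 0.01, adjustment computed over the filter-passing tests.
    """
    out = results.copy()
    out["adjusted_p"] = np.nan
    tested = out["passed_count_filter"] & out["p_value"].notna()
    if tested.any():
        out.loc[tested, "adjusted_p"] = adjust_bh(out.loc[tested, "p_value"])
    fold = out["fold_change"]
    if mode == "tss":
        effect = (fold - 1.0).abs() > 0.2
        sig = effect & (out["p_value"] < 0.05)
    elif mode == "dnase":
        effect = (fold >= 2.0) | (fold <= 0.5)
        sig = effect & (out["adjusted_p"] < 0.01)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["significant"] = (sig & tested).fillna(False)
    return out
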