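"""Log-log regression of transcriptional change on histone-mark changes.

Fold changes are strongly right-skewed, so every variable is log2
transformed before ordinary least squares; the slopes are then
elasticities (a 1% change in x gives a beta1% change in y).  Multiple
models are pruned by stepwise AIC; fit quality is judged by the standard
diagnostics (residuals vs fitted, Q-Q, leverage, Cook's distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

PSEUDOCOUNT = 0.5


def rna_fold_change(
    intronic: pd.DataFrame,
    orf: pd.DataFrame,
    rest_cols: list[str],
    stim_cols: list[str],
) -> pd.DataFrame:
    """Per-gene transcription-rate fold change (stimulated / resting).

    The intronic-read ratio (pseudocount 0.5 each side) is the primary
    estimate; genes with no intronic reads in either condition fall back
    to the ratio of reads over their ORF.  Genes absent from both tables
    are dropped with a log entry.  Returns fold plus a provenance flag.
    """
    genes = intronic.index.union(orf.index)
    folds, source = {}, {}
    for gene in genes:
        if gene in intronic.index:
            i_rest = float(intronic.loc[gene, rest_cols].mean())
            i_stim = float(intronic.loc[gene, stim_cols].mean())
        else:
            i_rest = i_stim = 0.0
        if i_rest + i_stim > 0:
            folds[gene] = (i_stim + PSEUDOCOUNT) / (i_rest + PSEUDOCOUNT)
            source[gene] = "intronic"
        elif gene in orf.index:
            o_rest = float(orf.loc[gene, rest_cols].mean())
            o_stim = float(orf.loc[gene, stim_cols].mean())
            folds[gene] = (o_stim + PSEUDOCOUNT) / (o_rest + PSEUDOCOUNT)
            source[gene] = "orf"
    return pd.DataFrame({"fold_change": pd.Series(folds), "source": pd.Series(source)})


def skewness(x, kind: int = 3) -> float:
    """Sample skewness; the default (type 3) is the moment coefficient
    ``g1 * ((n-1)/n)**1.5`` as reported by the common R implementation.
    Types 1 (g1) and 2 (bias-adjusted G1) are available."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        return np.nan
    g1 = stats.skew(x, bias=True)
    if kind == 1:
        return float(g1)
    if kind == 2:
        return float(g1 * np.sqrt(n * (n - 1)) / (n - 2))
    if kind == 3:
        return float(g1 * ((n - 1) / n) ** 1.5)
    raise ValueError(f"unknown skewness type {kind}")


@dataclass
class RegressionModel:
    """An OLS fit on log2-transformed variables, with diagnostics."""

    response: str
    terms: list[str]
    coefficients: pd.Series  # includes "Intercept"
    bse: pd.Series
    r_squared: float
    adj_r_squared: float
    aic: float
    residual_var: float
    n_obs: int
    fit: object = field(repr=False, default=None)  # statsmodels result
    design: pd.DataFrame = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def _aic(result) -> float:
    """n*ln(RSS/n) + 2(k+1): the model-selection convention that drops
    additive constants (only differences matter)."""
    n = int(result.nobs)
    rss = float(result.ssr)
    k = len(result.params)
    return n * np.log(rss / n) + 2 * k


def _fit_ols(y: np.ndarray, design: pd.DataFrame, response: str) -> RegressionModel:
    X = sm.add_constant(design, has_constant="add")
    X = X.rename(columns={"const": "Intercept"})
    res = sm.OLS(y, X).fit()
    return RegressionModel(
        response=response,
        terms=list(design.columns),
        coefficients=res.params,
        bse=res.bse,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        aic=_aic(res),
        residual_var=float(res.ssr / res.df_resid) if res.df_resid > 0 else np.nan,
        n_obs=int(res.nobs),
        fit=res,
        design=design,
        y=np.asarray(y, dtype=float),
    )


def loglog_fit(
    y: pd.Series,
    X: pd.DataFrame,
    already_log: bool = False,
    response: str = "rna_fc",
) -> RegressionModel:
    """OLS of log2(y) on log2(X) (single or multiple predictors)."""
    if not already_log:
        if (np.asarray(y) <= 0).any() or (X.to_numpy() <= 0).any():
            raise ValueError("variables must be strictly positive before log transform")
        y = np.log2(np.asarray(y, dtype=float))
        X = np.log2(X.astype(float))
    else:
        y = np.asarray(y, dtype=float)
    return _fit_ols(y, pd.DataFrame(X), response)


def per_mark_r2(y: pd.Series, X: pd.DataFrame, already_log: bool = False) -> pd.Series:
    """R² of each single-predictor log-log fit (one mark at a time)."""
    return pd.Series(
        {m: loglog_fit(y, X[[m]], already_log=already_log).r_squared for m in X.columns}
    )


def _interaction_design(X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            out[f"{a}:{b}"] = X[a] * X[b]
    return out


def stepwise_aic(
    y: pd.Series,
    X: pd.DataFrame,
    direction: str = "both",
    include_interactions: bool = False,
    already_log: bool = False,
    max_steps: int = 100,
) -> RegressionModel:
    """Greedy AIC-minimizing add/drop selection over candidate terms.

    Starts from the intercept-only model; at each step the single add (or,
    for ``direction="both"``/``"backward"``, drop) most reducing AIC is
    taken; stops at a local minimum.  Ties break deterministically by term
    order.  Rank-deficient additions (terms adding no new column rank) are
    skipped with a warning-level log, so duplicated columns are never
    selected.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate term")
    if not already_log:
        if (np.asarray(y) <= 0).any() or (X.to_numpy() <= 0).any():
            raise ValueError("variables must be strictly positive before log transform")
        y = np.log2(np.asarray(y, dtype=float))
        X = np.log2(X.astype(float))
    else:
        y = np.asarray(y, dtype=float)
    if include_interactions:
        X = _interaction_design(pd.DataFrame(X))
    X = pd.DataFrame(X)

    current: list[str] = []
    best = _fit_ols(y, X[current], "stepwise")
    for _ in range(max_steps):
        candidates: list[tuple[float, str, str]] = []
        if direction in ("both", "forward"):
            for term in X.columns:
                if term in current:
                    continue
                trial_cols = current + [term]
                trial = X[trial_cols].to_numpy()
                if np.linalg.matrix_rank(np.column_stack([np.ones(len(trial)), trial])) \
                        <= len(current) + 1:
                    continue  # adds no rank (collinear/duplicated term)
                candidates.append((_fit_ols(y, X[trial_cols], "stepwise").aic, "add", term))
        if direction in ("both", "backward"):
            for term in current:
                trial_cols = [t for t in current if t != term]
                candidates.append((_fit_ols(y, X[trial_cols], "stepwise").aic, "drop", term))
        if not candidates:
            break
        aic_best, action, term = min(candidates, key=lambda c: (c[0],))
        if aic_best >= best.aic - 1e-10:
            break
        current = current + [term] if action == "add" else [t for t in current if t != term]
        best = _fit_ols(y, X[current], "stepwise")
    return best


def model_diagnostics(model: RegressionModel) -> pd.DataFrame:
    """Residuals, fitted values, Q-Q quantiles, leverage, Cook's distance.

    Cook's distance uses D_i = r_i^2 h_i / (p s^2 (1−h_i)^2) with
    s^2 = RSS/(n−p), algebraically identical to the coefficient shift under
    leave-one-out refitting.
    """
    res = model.fit
    n, p = int(res.nobs), len(res.params)
    if n <= p:
        raise ValueError("leverages undefined: n <= number of parameters")
    infl = res.get_influence()
    h = infl.hat_matrix_diag
    e = res.resid
    s2 = res.ssr / res.df_resid
    cooks = e**2 * h / (p * s2 * (1.0 - h) ** 2)
    order = np.argsort(np.argsort(e))
    theo = stats.norm.ppf((order + 0.5) / n)
    return pd.DataFrame(
        {
            "fitted": res.fittedvalues,
            "residual": e,
            "std_residual": e / np.sqrt(s2 * (1.0 - h)),
            "theoretical_quantile": theo,
            "leverage": h,
            "cooks_distance": cooks,
        },
        index=model.design.index,
    )


def induction_class_summary(rna_fold: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Median/quartile RNA induction per metaprofile class (the boxplot
    summary linking leading-mark induction strength to transcription)."""
    rows = []
    for cls, ids in classes[classes != ""].groupby(classes).groups.items():
        vals = rna_fold.reindex(ids).dropna()
        if len(vals) == 0:
            continue
        rows.append((cls, len(vals), vals.median(),
                     vals.quantile(0.25), vals.quantile(0.75)))
    return pd.DataFrame(rows, columns=["class", "n", "median", "q25", "q75"]
                        ).set_index("class")
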