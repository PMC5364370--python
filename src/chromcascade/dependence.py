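"""Two-background fold-change asymmetry: how much of the induction seen in
one genetic background depends on a factor missing in another.

Each region contributes a point X = log2 induction fold in background 1,
Y = X − log2 induction fold in background 2.  Purely technical variation
is symmetric about Y = 0; systematic dependence on the second background's
genotype piles points above the axis.  The estimator reflects the
below-axis cloud about Y = 0 within X-bins to form a null, counts the
above-axis excess per bin, flags the most extreme above-axis points up to
that excess, and iterates until the remaining cloud passes a sign test.
The per-region flags are bookkeeping, not per-region significance calls —
only the aggregate count is interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DependencePoints:
    """Matched per-region coordinates of the asymmetry plot."""

    x: pd.Series  # log2 fold change in background 1
    y: pd.Series  # x − log2 fold change in background 2
    background_pair: tuple[str, str] = ("bg1", "bg2")


@dataclass
class DependenceEstimate:
    slope_above: float
    slope_below: float
    se_above: float
    se_below: float
    p_above: float
    p_below: float
    n_dependent: int
    flags: pd.Series  # bool per region
    background_pair: tuple[str, str]
    n_iterations: int = 0


def make_dependence_points(
    fc_bg1: pd.Series,
    fc_bg2: pd.Series,
    pair: tuple[str, str] = ("bg1", "bg2"),
) -> DependencePoints:
    """Build the asymmetry coordinates from two positive fold-change
    vectors over the same regions."""
    if not fc_bg1.index.equals(fc_bg2.index):
        raise ValueError("region sets differ between backgrounds")
    if (fc_bg1 <= 0).any() or (fc_bg2 <= 0).any():
        raise ValueError("fold changes must be positive")
    x = np.log2(fc_bg1)
    y = x - np.log2(fc_bg2)
    return DependencePoints(x=x, y=y, background_pair=pair)


def _side_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope (intercept fitted) with standard error and
    two-sided p for slope = 0.

    The intercept must be fitted: restricting to one side of the axis
    shifts the cloud's mean |Y| away from zero even for purely technical
    noise, and only the slope separates systematic dependence (which grows
    with X) from that shift.
    """
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0 or n < 3:
        return np.nan, np.nan, np.nan
    slope = float(np.dot(xc, y)) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    dof = n - 2
    s2 = float(np.dot(resid, resid)) / dof
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return slope, 0.0, 0.0 if slope != 0 else 1.0
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return slope, se, p


def fit_asymmetry_regression(points: DependencePoints, min_points: int = 10):
    """Separate linear regressions for the above- and below-axis clouds.
    Returns a dict with slope/SE/p per side (NaN-flagged when a side has
    fewer than ``min_points``)."""
    x, y = points.x.to_numpy(), points.y.to_numpy()
    out = {}
    for side, mask in (("above", y > 0), ("below", y < 0)):
        if mask.sum() < min_points:
            out[side] = {"slope": np.nan, "se": np.nan, "p": np.nan, "n": int(mask.sum())}
            continue
        slope, se, p = _side_regression(x[mask], y[mask])
        out[side] = {"slope": slope, "se": se, "p": p, "n": int(mask.sum())}
    return out


def _sign_test_p(y: np.ndarray, alternative: str = "two-sided") -> float:
    nonzero = y[y != 0]
    if len(nonzero) == 0:
        return 1.0
    k = int((nonzero > 0).sum())
    return stats.binomtest(k, len(nonzero), 0.5, alternative=alternative).pvalue


def estimate_dependent_set(
    points: DependencePoints,
    n_bins: int = 5,
    sign_p_stop: float = 0.05,
    max_iter: int = 100,
    bin_values: np.ndarray | pd.Series | None = None,
) -> DependenceEstimate:
    """Estimate how many regions' induction depends on the second
    background, with per-region bookkeeping flags.

    Within X-quantile bins the below-axis cloud is reflected about Y = 0 as
    the technical null and the per-bin dependent count is
    ``max(0, n_above − n_below)``; the summed count is then assigned to
    the most-extreme above-axis points.  "Most extreme" is taken at fixed
    X, i.e. by Y − X (the negated second-background induction): Y itself
    shares the first background's measurement noise with X, so ranking by
    raw Y would preferentially flag whichever regions happened to be
    over-measured in background 1.  For the same reason ``bin_values``
    should be supplied when an induction-strength measurement independent
    of Y's noise is available (e.g. from a held-out replicate): binning on
    X itself conditions on the shared noise and tilts the within-bin null
    away from symmetry.  Flagged points are removed and the remainder
    re-tested for sign symmetry; the procedure iterates until symmetric
    (sign-test p above ``sign_p_stop``) or no excess remains.
    """
    x = points.x.to_numpy()
    y = points.y.to_numpy()
    n = len(x)
    if n == 0:
        raise ValueError("no points")
    bv = x if bin_values is None else np.asarray(bin_values, dtype=float)
    edges = np.quantile(bv, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_of = np.clip(np.searchsorted(edges, bv, side="right") - 1, 0, n_bins - 1)

    flags = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    n_iter = 0
    while True:
        n_iter += 1
        if n_iter > max_iter:
            raise RuntimeError(
                f"dependent-set estimation did not stabilize in {max_iter} rounds "
                f"(flagged={int(flags.sum())}, remaining sign-test p="
                f"{_sign_test_p(y[active]):.3g})"
            )
        budget = 0
        for b in range(n_bins):
            in_bin = active & (bin_of == b)
            budget += max(0, int((in_bin & (y > 0)).sum())
                          - int((in_bin & (y < 0)).sum()))
        if budget == 0:
            break
        idx = np.flatnonzero(active & (y > 0))
        take = idx[np.argsort(-(y[idx] - x[idx]), kind="stable")[:budget]]
        if len(take) == 0:
            break
        flags[take] = True
        active[take] = False
        # one-sided: keep iterating only while the remainder is still
        # above-heavy (removal itself makes the cloud below-heavy)
        if _sign_test_p(y[active], "greater") > sign_p_stop:
            break

    reg = fit_asymmetry_regression(points)
    return DependenceEstimate(
        slope_above=reg["above"]["slope"], slope_below=reg["below"]["slope"],
        se_above=reg["above"]["se"], se_below=reg["below"]["se"],
        p_above=reg["above"]["p"], p_below=reg["below"]["p"],
        n_dependent=int(flags.sum()),
        flags=pd.Series(flags, index=points.x.index),
        background_pair=points.background_pair,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Restoration classification across Elk-1 variants
# ---------------------------------------------------------------------------

RESTORATION_CLASSES = (
    "not-dependent",
    "dependent-not-restored",
    "restored-any-Elk1",
    "restored-requires-phospho+FW",
)


def dependence_flags_by_pair(
    fc_by_background: dict[str, pd.DataFrame],
    reference_background: str = "WT",
    n_bins: int = 5,
) -> dict[str, pd.DataFrame]:
    """Run the dependent-set estimator for every background against the
    reference, independently per mark.  Returns per-pair region x mark
    boolean flag tables."""
    ref = fc_by_background[reference_background]
    out: dict[str, pd.DataFrame] = {}
    for bg, fc in fc_by_background.items():
        if bg == reference_background:
            continue
        flags = {}
        for mark in ref.columns:
            pts = make_dependence_points(ref[mark], fc[mark], (reference_background, bg))
            flags[mark] = estimate_dependent_set(pts, n_bins=n_bins).flags
        out[bg] = pd.DataFrame(flags)
    return out


def _pair_offset(anchor_fc, reference_background, bg) -> float:
    """Technical Y offset of a background pair, estimated from regions
    without induction (detected but unchanged): any residual scaling error
    shifts their whole Y cloud coherently, and they carry no dependence
    signal to confound the estimate."""
    ref = np.log2(anchor_fc[reference_background])
    y = (ref - np.log2(anchor_fc[bg])).mean(axis=1)
    return float(y.median())


def tss_dependence_flags(
    fc_by_background: dict[str, pd.DataFrame],
    reference_background: str = "WT",
    n_bins: int = 5,
    anchor_fc_by_background: dict[str, pd.DataFrame] | None = None,
    bin_values: pd.Series | None = None,
) -> dict[str, pd.Series]:
    """Per-TSS dependence flags from mark-averaged asymmetry points.

    Per-mark flag unions are dominated by the weakly-moving marks, whose
    above-axis excess is real but whose extreme-Y ranking is mostly noise;
    averaging the asymmetry coordinate over the five marks shrinks the
    technical noise by ~sqrt(5) while every truly dependent region keeps a
    positive displacement, so one estimator run per background pair on the
    averaged points gives far better-calibrated TSS-level flags.

    ``anchor_fc_by_background`` (fold changes over detected-but-unchanged
    regions) re-centers each pair's Y at zero before estimation,
    removing the coherent offset left by per-sample scaling error.
    """
    ref = np.log2(fc_by_background[reference_background])
    x_mean = ref.mean(axis=1)
    out: dict[str, pd.Series] = {}
    for bg, fc in fc_by_background.items():
        if bg == reference_background:
            continue
        y_mean = (ref - np.log2(fc)).mean(axis=1)
        if anchor_fc_by_background is not None:
            y_mean = y_mean - _pair_offset(anchor_fc_by_background,
                                           reference_background, bg)
        pts = DependencePoints(x=x_mean, y=y_mean,
                               background_pair=(reference_background, bg))
        out[bg] = estimate_dependent_set(pts, n_bins=n_bins,
                                         bin_values=bin_values).flags
    return out


def combined_pair_flags(
    fc_by_background: dict[str, pd.DataFrame],
    backgrounds: tuple[str, ...],
    reference_background: str = "WT",
    n_bins: int = 5,
    anchor_fc_by_background: dict[str, pd.DataFrame] | None = None,
    bin_values: pd.Series | None = None,
) -> pd.Series:
    """Dependence flags from asymmetry averaged over several background
    pairs (and over marks).

    Used for the Elk-1 variant pairs, which probe the same biological
    question twice: averaging their asymmetry coordinates before flagging
    halves the technical variance, where demanding two independent noisy
    flags would multiply the miss rates.
    """
    ref = np.log2(fc_by_background[reference_background])
    x_mean = ref.mean(axis=1)
    ys = []
    for bg in backgrounds:
        y = (ref - np.log2(fc_by_background[bg])).mean(axis=1)
        if anchor_fc_by_background is not None:
            y = y - _pair_offset(anchor_fc_by_background, reference_background, bg)
        ys.append(y)
    y_mean = pd.concat(ys, axis=1).mean(axis=1)
    pts = DependencePoints(x=x_mean, y=y_mean,
                           background_pair=(reference_background, "+".join(backgrounds)))
    return estimate_dependent_set(pts, n_bins=n_bins, bin_values=bin_values).flags


def classify_restoration(
    flags_by_pair: dict[str, pd.DataFrame],
    tko: str = "TKO",
    elk1: str = "TKO+Elk1",
    non_a: str = "TKO+Elk1nonA",
    delta_fw: str = "TKO+Elk1dFW",
    variants_combined: pd.Series | None = None,
) -> pd.Series:
    """Per-TSS restoration class from the pairwise dependence flags.

    A TSS is TCF-dependent when flagged (any mark) in the WT-vs-TKO pair.
    Dependent TSSs not flagged against TKO+Elk-1 are restored; restored
    TSSs that remain dependent against the phospho-site mutant and the
    FW-motif-deleted variant require phosphorylation and Mediator
    recruitment.  When ``variants_combined`` (flags from the averaged
    variant-pair asymmetry, :func:`combined_pair_flags`) is supplied it
    replaces the noisier requirement of two separate per-pair flags.
    """
    for bg in (tko, elk1, non_a, delta_fw):
        if bg not in flags_by_pair:
            raise ValueError(f"missing background pair vs {bg!r}")

    def _tss_level(flags) -> pd.Series:
        return flags.any(axis=1) if isinstance(flags, pd.DataFrame) else flags

    dep = _tss_level(flags_by_pair[tko])
    dep_elk1 = _tss_level(flags_by_pair[elk1])
    if variants_combined is not None:
        needs_phospho_fw = variants_combined.reindex(dep.index)
    else:
        needs_phospho_fw = (_tss_level(flags_by_pair[non_a])
                            & _tss_level(flags_by_pair[delta_fw]))

    cls = pd.Series("not-dependent", index=dep.index, dtype=object)
    cls[dep & dep_elk1] = "dependent-not-restored"
    restored = dep & ~dep_elk1
    cls[restored & ~needs_phospho_fw] = "restored-any-Elk1"
    cls[restored & needs_phospho_fw] = "restored-requires-phospho+FW"
    return cls
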