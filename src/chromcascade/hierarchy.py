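"""Mark-induction hierarchy: fold changes, Distance Index, dendrograms, and
multiscale-bootstrap cluster support.

The Distance Index quantifies how much less a comparison mark moves than a
leading mark: over regions where the leading mark's linear fold change
exceeds 1, it is the mean of (leading fold − comparison fold), reported in
percentage points.  Mark dendrograms use single-linkage agglomeration of
Euclidean distances between per-mark fold-change vectors; cluster support
is assessed by multiscale bootstrap: the bootstrap probability of each
edge is measured at several resample sizes and extrapolated through the
signed-distance/curvature fit to the approximately-unbiased (AU) p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.stats import norm
from sklearn.metrics import silhouette_score

from .core import CountMatrix

PSEUDOCOUNT = 0.5
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


def compute_fold_changes(
    normalized: dict[str, CountMatrix],
    rest: tuple[str, int] = ("FCS", 0),
    stim: tuple[str, int] = ("TPA", 30),
    background: str = "WT",
    replicate: int | None = None,
) -> pd.DataFrame:
    """Region x mark table of pseudocounted induction ratios.

    x = (mean normalized stimulated + 0.5) / (mean normalized resting + 0.5),
    replicates averaged after scaling (or a single replicate when
    ``replicate`` is given).
    """
    cols = {}
    for mark, cm in normalized.items():
        sub = cm.select(background=background) if "background" in cm.samples else cm
        if replicate is not None:
            sub = sub.select(replicate=replicate)
        mean_rest = sub.condition_mean(*rest)
        mean_stim = sub.condition_mean(*stim)
        cols[mark] = (mean_stim + PSEUDOCOUNT) / (mean_rest + PSEUDOCOUNT)
    return pd.DataFrame(cols)


def distance_index(fc_table: pd.DataFrame, leading_mark: str) -> tuple[pd.Series, int]:
    """DI row for one leading mark, in percentage points.

    Restricted to regions where the leading mark's fold change is
    strictly above 1; DI(y) = 100 * mean(x_i − y_i).  Returns the row and
    the number of qualifying regions (0 regions → all-NaN row, flagged by
    the count).
    """
    if fc_table.empty:
        raise ValueError("empty fold-change table")
    x = fc_table[leading_mark]
    qualifying = x > 1.0
    n = int(qualifying.sum())
    row = pd.Series(np.nan, index=fc_table.columns, name=leading_mark)
    if n == 0:
        return row, 0
    sub = fc_table.loc[qualifying]
    for mark in fc_table.columns:
        row[mark] = 100.0 * (sub[leading_mark] - sub[mark]).mean()
    return row, n


def di_matrix(fc_table: pd.DataFrame) -> pd.DataFrame:
    """Full leading-by-comparison DI matrix (diagonal exactly 0).

    Each row is computed over its own leading mark's qualifying regions,
    so the matrix is not antisymmetric in general.
    """
    rows = [distance_index(fc_table, m)[0] for m in fc_table.columns]
    return pd.DataFrame(rows, index=fc_table.columns)


# ---------------------------------------------------------------------------
# Mark clustering
# ---------------------------------------------------------------------------

def _pair_columns(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def cluster_marks(fc_table: pd.DataFrame, method: str = "single",
                  log_scale: bool = False) -> tuple[np.ndarray, list[str]]:
    """Agglomerative dendrogram over marks from Euclidean distances between
    per-mark fold-change vectors.  Returns (scipy linkage matrix, labels)."""
    if fc_table.shape[1] < 2:
        raise ValueError("need at least 2 marks")
    values = fc_table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("fold-change table contains NaN")
    if log_scale:
        values = np.log2(values)
    z = sch.linkage(values.T, method=method, metric="euclidean")
    return z, list(fc_table.columns)


def cluster_subsets(z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """The nested label subsets (one per internal edge) of a dendrogram."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    subsets = []
    for k, (a, b, _, _) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        subsets.append(merged)
    return subsets


def to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a newick string (branch lengths from
    merge heights)."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(z, labels)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Multiscale bootstrap AU
# ---------------------------------------------------------------------------

@dataclass
class AUResult:
    """Per-edge cluster support from multiscale bootstrap."""

    edges: list[frozenset]
    au: pd.Series  # edge label -> AU p-value
    bp: pd.Series  # ordinary bootstrap probability (at scale 1)
    v: pd.Series  # signed distance
    c: pd.Series  # curvature
    scales: tuple[float, ...]
    bp_table: pd.DataFrame  # edge x scale bootstrap probabilities


def _edge_key(edge: frozenset) -> str:
    return "+".join(sorted(edge))


def multiscale_au(
    fc_table: pd.DataFrame,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "single",
    extra_edges: list[frozenset] | None = None,
    log_scale: bool = False,
) -> AUResult:
    """AU/BP support for every edge of the mark dendrogram.

    For each scale rho, ``ceil(rho*n)`` regions are drawn with replacement
    (realized as multinomial region weights), marks are reclustered, and
    each reference edge's presence frequency BP_rho recorded.  The
    extrapolation fit is weighted least squares of
    ``z(rho) = Phi^-1(1 − BP_rho) = v*sqrt(rho) + c/sqrt(rho)`` with
    binomial-variance weights; AU = 1 − Phi(v − c).  Edges at BP 0 or 1
    across every scale are pinned to that value.
    """
    n_regions, n_marks = fc_table.shape
    if n_regions < 3:
        raise ValueError("need at least 3 regions for bootstrap support")
    values = fc_table.to_numpy(dtype=float)
    if log_scale:
        values = np.log2(values)
    labels = list(fc_table.columns)
    z_ref, _ = cluster_marks(fc_table, method=method, log_scale=log_scale)
    edges = cluster_subsets(z_ref, labels)
    for extra in extra_edges or []:
        if extra not in edges:
            edges.append(frozenset(extra))

    pairs = _pair_columns(n_marks)
    sq = np.stack([(values[:, i] - values[:, j]) ** 2 for i, j in pairs], axis=1)

    rng = np.random.default_rng(seed)
    bp_table = np.zeros((len(edges), len(scales)))
    uniform = np.full(n_regions, 1.0 / n_regions)
    for si, rho in enumerate(scales):
        n_prime = int(np.ceil(rho * n_regions))
        weights = rng.multinomial(n_prime, uniform, size=n_boot)
        d2 = weights.astype(float) @ sq  # n_boot x n_pairs condensed
        d = np.sqrt(d2)
        hits = np.zeros(len(edges))
        for b in range(n_boot):
            z_b = sch.linkage(d[b], method=method)
            subsets = set(cluster_subsets(z_b, labels))
            for ei, edge in enumerate(edges):
                if edge in subsets:
                    hits[ei] += 1
        bp_table[:, si] = hits / n_boot

    sqrt_rho = np.sqrt(np.asarray(scales, dtype=float))
    au, bp1, vs, cs = {}, {}, {}, {}
    for ei, edge in enumerate(edges):
        key = _edge_key(edge)
        bps = bp_table[ei]
        usable = (bps > 0.0) & (bps < 1.0)
        if usable.sum() < 2:
            pinned = 1.0 if bps.mean() >= 0.5 else 0.0
            au[key], bp1[key] = pinned, pinned
            vs[key], cs[key] = np.nan, np.nan
            continue
        zq = norm.ppf(1.0 - bps[usable])
        X = np.column_stack([sqrt_rho[usable], 1.0 / sqrt_rho[usable]])
        w = n_boot * norm.pdf(zq) ** 2 / (bps[usable] * (1.0 - bps[usable]))
        wsqrt = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * wsqrt[:, None], zq * wsqrt, rcond=None)
        v, c = float(coef[0]), float(coef[1])
        au[key] = float(1.0 - norm.cdf(v - c))
        bp1[key] = float(1.0 - norm.cdf(v + c))
        vs[key], cs[key] = v, c

    keys = [_edge_key(e) for e in edges]
    return AUResult(
        edges=edges,
        au=pd.Series(au).reindex(keys),
        bp=pd.Series(bp1).reindex(keys),
        v=pd.Series(vs).reindex(keys),
        c=pd.Series(cs).reindex(keys),
        scales=tuple(scales),
        bp_table=pd.DataFrame(bp_table, index=keys, columns=list(scales)),
    )


# ---------------------------------------------------------------------------
# Exploratory TSS clustering
# ---------------------------------------------------------------------------

def cluster_tss_regions(
    fc_table: pd.DataFrame,
    n_changed_marks: pd.Series,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> pd.DataFrame:
    """Ward clustering of TSS regions within groups defined by how many
    marks changed; reports silhouette summaries only (exploratory)."""
    rows = []
    for n_changed, ids in n_changed_marks.groupby(n_changed_marks).groups.items():
        sub = fc_table.loc[fc_table.index.intersection(ids)]
        if len(sub) < 3:
            continue
        z = sch.linkage(sub.to_numpy(), method="ward")
        for k in k_range:
            if k >= len(sub):
                continue
            assign = sch.fcluster(z, t=k, criterion="maxclust")
            if len(np.unique(assign)) < 2:
                sil = np.nan
            else:
                sil = silhouette_score(sub.to_numpy(), assign)
            rows.append((n_changed, k, sil, len(sub)))
    return pd.DataFrame(rows, columns=["n_changed_marks", "k", "silhouette", "n_regions"])
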