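"""Per-base average density profiles around anchors, difference profiles,
and induction-class grouping.

Profiles are strand-oriented (minus-strand anchors are mirrored so
positive coordinates always point downstream of transcription), averaged
across anchors, smoothed with a centered 51-bp moving average (truncated
windows at the edges), and the nucleosome-depleted ±150 bp core is masked
with NaN — a sentinel, never zero, so difference profiles cannot
fabricate signal there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import TSSRegion

logger = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """Mean normalized density per position relative to the anchors."""

    positions: np.ndarray  # −flank..+flank inclusive
    values: np.ndarray  # NaN inside the masked core
    n_regions: int
    smooth: int = 51
    mask: int = 150

    def geometry(self) -> tuple:
        return (len(self.positions), int(self.positions[0]), self.smooth, self.mask)


def _boxcar(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges (the
    divisor is the number of in-range positions, so a flat input stays
    flat)."""
    if width <= 1:
        return values.copy()
    kernel = np.ones(width)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def compute_metaprofile(
    coverage: dict[str, np.ndarray],
    anchors: list[TSSRegion],
    flank: int = 3000,
    smooth: int = 51,
    mask: int = 150,
) -> MetaProfile:
    """Strand-oriented mean per-base density across anchors.

    Anchors whose window runs off the contig are skipped with a log entry.
    Averaging precedes smoothing (equivalent for a linear smoother).
    """
    width = 2 * flank + 1
    acc = np.zeros(width)
    n_used = 0
    for anchor in anchors:
        arr = coverage.get(anchor.chrom)
        lo, hi = anchor.tss_position - flank, anchor.tss_position + flank + 1
        if arr is None or lo < 0 or hi > len(arr):
            logger.info("anchor %s window off contig; skipped", anchor.region_id)
            continue
        window = arr[lo:hi]
        acc += window[::-1] if anchor.strand == "-" else window
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable anchors")
    mean = acc / n_used
    smoothed = _boxcar(mean, smooth)
    positions = np.arange(-flank, flank + 1)
    smoothed[np.abs(positions) <= mask] = np.nan
    return MetaProfile(positions, smoothed, n_used, smooth, mask)


def difference_profile(stim: MetaProfile, rest: MetaProfile) -> MetaProfile:
    """Elementwise stimulated − resting; the masked core propagates."""
    if stim.geometry() != rest.geometry():
        raise ValueError("profile geometries differ")
    return MetaProfile(stim.positions.copy(), stim.values - rest.values,
                       min(stim.n_regions, rest.n_regions), stim.smooth, stim.mask)


def downstream_skew(profile: MetaProfile) -> float:
    """(downstream − upstream) / total absolute signal of a difference
    profile: 0 for symmetric induction, positive when the gain sits in the
    transcribed direction."""
    v = profile.values
    pos = profile.positions
    down = np.nansum(v[pos > 0])
    up = np.nansum(v[pos < 0])
    denom = np.nansum(np.abs(v))
    return float((down - up) / denom) if denom > 0 else 0.0


def group_by_induction(
    fc_table: pd.DataFrame,
    counts: pd.DataFrame,
    significant: pd.Series,
    leading_mark: str | None = None,
    min_reads_unchanged: float = 100.0,
) -> pd.Series:
    """Class labels for metaprofile grouping by leading-mark fold change.

    Significant regions: ``low`` [1, 1.5), ``medium`` [1.5, 2), ``high``
    [2, ∞).  The ``unchanged`` class is non-significant regions that are
    both adequately measured (mean read count across the TSS window at
    least ``min_reads_unchanged``) and genuinely flat (within the 20%
    no-change band) — a large but non-significant fold excludes a region
    from every class.  Everything else gets an empty label.
    """
    leading_mark = leading_mark or fc_table.columns[0]
    fold = fc_table[leading_mark]
    sig = significant.reindex(fc_table.index).fillna(False).astype(bool)
    mean_reads = counts.reindex(fc_table.index).mean(axis=1)

    labels = pd.Series("", index=fc_table.index, dtype=object)
    labels[sig & (fold >= 1.0) & (fold < 1.5)] = "low"
    labels[sig & (fold >= 1.5) & (fold < 2.0)] = "medium"
    labels[sig & (fold >= 2.0)] = "high"
    labels[~sig & (mean_reads >= min_reads_unchanged)
           & ((fold - 1.0).abs() <= 0.2)] = "unchanged"
    return labels
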