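"""Region model, file I/O, window assignment, and direct-target classification.

All coordinates are 0-based half-open (BED native).  The distance between a
point and an interval is zero when the point lies inside the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SAMPLE_META_COLUMNS, CountMatrix

logger = logging.getLogger(__name__)

TSS_UPSTREAM = 2000  # window extent upstream of the TSS
TSS_DOWNSTREAM = 1000  # and downstream, in the direction of transcription
SITE_FLANK = 2000  # half-width of the window centered on a site summit


@dataclass
class TSSRegion:
    """A transcription start site with its counting window.

    The analysis window spans −2 kb..+1 kb around the TSS in the direction
    of transcription, i.e. 3 kb total.  Windows running off the chromosome
    start are clipped and flagged.
    """

    region_id: str
    chrom: str
    tss_position: int
    strand: str
    gene_id: str = ""
    start: int = field(default=None)  # type: ignore[assignment]
    end: int = field(default=None)  # type: ignore[assignment]
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.start is None or self.end is None:
            assign_tss_window(self)


def assign_tss_window(region: TSSRegion) -> TSSRegion:
    """Attach the strand-oriented −2 kb..+1 kb window to ``region`` in place.

    Plus strand: ``[tss−2000, tss+1000)``; minus strand mirrors to
    ``[tss−1000, tss+2000)``.  Negative start coordinates are clipped to 0
    and the region's ``clipped`` flag is set.
    """
    if region.strand == "+":
        start, end = region.tss_position - TSS_UPSTREAM, region.tss_position + TSS_DOWNSTREAM
    elif region.strand == "-":
        start, end = region.tss_position - TSS_DOWNSTREAM, region.tss_position + TSS_UPSTREAM
    else:
        raise ValueError(f"unknown strand {region.strand!r} for {region.region_id}")
    if start < 0:
        logger.info("window for %s clipped at chromosome start", region.region_id)
        start = 0
        region.clipped = True
    region.start, region.end = start, end
    return region


@dataclass
class GenomicSite:
    """A point feature (DNase I HS summit, ChIP peak) with a ±2 kb window."""

    site_id: str
    chrom: str
    summit: int
    site_class: str = "unclassified"

    @property
    def start(self) -> int:
        return max(0, self.summit - SITE_FLANK)

    @property
    def end(self) -> int:
        return self.summit + SITE_FLANK


@dataclass(frozen=True)
class HiCLink:
    """A chromatin contact joining a TSS region to a peak site."""

    region_id: str
    site_id: str


# ---------------------------------------------------------------------------
# Count-table I/O: TSV with region_id as first column, plus a metadata
# sidecar TSV (sample_id, mark, background, condition, time, replicate).
# ---------------------------------------------------------------------------

def read_count_table(path, meta_path=None) -> CountMatrix:
    """Read a count TSV (and optional sample-metadata sidecar).

    Raises ``ValueError`` naming the offending row for duplicate region ids
    or non-integer counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate region_id {dup[0]!r} in {path}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals.index[pd.to_numeric(vals, errors="coerce").isna()][0]
            raise ValueError(f"non-numeric count at region {bad!r}, sample {col!r}")
    samples = None
    if meta_path is not None:
        samples = pd.read_csv(meta_path, sep="\t", index_col=0)
        missing = df.columns.difference(samples.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples {list(missing)}")
    return CountMatrix(df, samples)


def write_count_table(path, cm: CountMatrix, meta_path=None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="region_id")
    if meta_path is not None:
        cm.samples.to_csv(meta_path, sep="\t", index_label="sample_id",
                          columns=list(SAMPLE_META_COLUMNS))


def write_results(path, table: pd.DataFrame) -> None:
    """Write any per-region results table as TSV."""
    table.to_csv(path, sep="\t", index=True)


# ---------------------------------------------------------------------------
# BED6 / bedGraph / link-table I/O
# ---------------------------------------------------------------------------

def write_tss_bed(path, regions: list[TSSRegion]) -> None:
    rows = [
        (r.chrom, r.start, r.end, r.region_id, 0, r.strand) for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> list[TSSRegion]:
    """Read TSS regions from BED6; the TSS point is recovered from strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    regions = []
    for row in df.itertuples(index=False):
        tss = row.start + TSS_UPSTREAM if row.strand == "+" else row.end - TSS_UPSTREAM
        regions.append(TSSRegion(row.name, row.chrom, int(tss), row.strand,
                                 start=int(row.start), end=int(row.end)))
    return regions


def write_sites_bed(path, sites: list[GenomicSite]) -> None:
    rows = [(s.chrom, s.summit, s.summit + 1, s.site_id, 0, ".") for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> list[GenomicSite]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [GenomicSite(r.name, r.chrom, int(r.start)) for r in df.itertuples(index=False)]


def write_links(path, links: list[HiCLink]) -> None:
    pd.DataFrame([(l.region_id, l.site_id) for l in links],
                 columns=["region_id", "site_id"]).to_csv(path, sep="\t", index=False)


def read_links(path) -> list[HiCLink]:
    df = pd.read_csv(path, sep="\t")
    return [HiCLink(r.region_id, r.site_id) for r in df.itertuples(index=False)]


def write_bedgraph(path, coverage: dict[str, np.ndarray]) -> None:
    """Write dense per-base coverage as run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            vals = np.asarray(coverage[chrom])
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Read bedGraph into dense per-base arrays (one per chromosome)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    out: dict[str, np.ndarray] = {}
    sizes = dict(chrom_sizes or {})
    for chrom, sub in df.groupby("chrom", sort=False):
        size = sizes.get(chrom, int(sub["end"].max()))
        arr = np.zeros(size, dtype=float)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[int(s):int(e)] = v
        out[chrom] = arr
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _nearest_point_distance(
    queries: list[tuple[str, int]], points: list[tuple[str, int]]
) -> np.ndarray:
    """Distance from each query point to the nearest reference point on the
    same chromosome (inf when the chromosome holds no reference point)."""
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in points:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    dist = np.full(len(queries), np.inf)
    for i, (chrom, pos) in enumerate(queries):
        ref = by_chrom.get(chrom)
        if ref is None:
            continue
        j = np.searchsorted(ref, pos)
        cands = []
        if j < len(ref):
            cands.append(abs(ref[j] - pos))
        if j > 0:
            cands.append(abs(ref[j - 1] - pos))
        dist[i] = min(cands)
    return dist


def classify_direct_targets(
    tss_regions: list[TSSRegion],
    srf_peaks: list[GenomicSite],
    hic_links: list[HiCLink] | None = None,
    distance: int = 10_000,
) -> pd.Series:
    """Label each TSS ``direct`` or ``indirect`` with respect to SRF control.

    A TSS is a direct target when its TSS point lies within ``distance``
    (default 10 kb) of the nearest SRF peak summit, or when a chromatin
    contact links it to an SRF peak.  An empty peak set yields all-indirect.
    """
    peak_ids = {p.site_id for p in srf_peaks}
    linked = {l.region_id for l in (hic_links or []) if l.site_id in peak_ids}
    dist = _nearest_point_distance(
        [(r.chrom, r.tss_position) for r in tss_regions],
        [(p.chrom, p.summit) for p in srf_peaks],
    )
    labels = [
        "direct" if (d <= distance or r.region_id in linked) else "indirect"
        for r, d in zip(tss_regions, dist)
    ]
    return pd.Series(labels, index=[r.region_id for r in tss_regions], name="target_class")


def classify_dnase_sites(
    sites: list[GenomicSite],
    tss_regions: list[TSSRegion],
    srf_peaks: list[GenomicSite],
    tss_distance: int = 2000,
    srf_overlap: int = 200,
) -> pd.Series:
    """Classify DNase I HS sites: TSS-proximal (summit within 2 kb of any
    TSS), remote with an SRF peak (summit within ``srf_overlap`` of a peak
    summit), or remote-other."""
    tss_dist = _nearest_point_distance(
        [(s.chrom, s.summit) for s in sites],
        [(r.chrom, r.tss_position) for r in tss_regions],
    )
    srf_dist = _nearest_point_distance(
        [(s.chrom, s.summit) for s in sites],
        [(p.chrom, p.summit) for p in srf_peaks],
    )
    labels = []
    for d_tss, d_srf in zip(tss_dist, srf_dist):
        if d_tss <= tss_distance:
            labels.append("TSS-proximal")
        elif d_srf <= srf_overlap:
            labels.append("remote-SRF")
        else:
            labels.append("remote-other")
    return pd.Series(labels, index=[s.site_id for s in sites], name="site_class")
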