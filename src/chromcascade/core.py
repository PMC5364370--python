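"""Shared constants and the count-matrix container used across all stages.

The five combinatorial histone-modification epitopes are kept in their
induction-hierarchy order (most to least responsive): the phospho-acetyl
mark leads, tri-methylation trails.  All stages that iterate "in mark
order" use :data:`MARKS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Histone marks in hierarchy order (leading mark first).
MARKS: tuple[str, ...] = (
    "H3K9acS10ph",
    "H4K16ac",
    "H3K27ac",
    "H3K9acK14ac",
    "H3K4me3",
)

#: Genetic backgrounds: wild type, TCF triple knockout, and TKO
#: reconstituted with Elk-1 variants (wild type, phospho-site mutant,
#: Mediator-recruitment-motif deletion).
BACKGROUNDS: tuple[str, ...] = (
    "WT",
    "TKO",
    "TKO+Elk1",
    "TKO+Elk1nonA",
    "TKO+Elk1dFW",
)

#: Stimulation conditions: serum-starved resting state and TPA time points
#: (minutes after phorbol-ester addition).
CONDITIONS: tuple[tuple[str, int], ...] = (
    ("FCS", 0),
    ("TPA", 5),
    ("TPA", 15),
    ("TPA", 30),
)

N_REPLICATES = 2

SAMPLE_META_COLUMNS = ("mark", "background", "condition", "time", "replicate")


def sample_name(background: str, condition: str, time: int, replicate: int) -> str:
    return f"{background}_{condition}{time}_r{replicate}"


@dataclass
class CountMatrix:
    """Per-region read counts with aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by region id, one column per sample.  Raw counts
        are integer; normalized matrices are real-valued.
    samples
        DataFrame indexed by sample id with columns ``mark``,
        ``background``, ``condition``, ``time``, ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                index=self.counts.columns, columns=list(SAMPLE_META_COLUMNS)
            )
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate region id: {dup!r}")
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"sample metadata missing for {list(missing)}")
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def region_ids(self) -> pd.Index:
        return self.counts.index

    def select(self, **criteria) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. ``select(background="WT")``."""
        mask = np.ones(len(self.samples), dtype=bool)
        for key, value in criteria.items():
            col = self.samples[key]
            mask &= (col == value).to_numpy() if not isinstance(value, (list, tuple, set)) else col.isin(value).to_numpy()
        cols = self.samples.index[mask]
        return CountMatrix(self.counts[cols], self.samples.loc[cols].copy())

    def scaled(self, factors: pd.Series) -> "CountMatrix":
        """Multiply each sample column by its scaling factor."""
        missing = self.counts.columns.difference(factors.index)
        if len(missing):
            raise ValueError(f"no factor for samples {list(missing)}")
        out = self.counts * factors.reindex(self.counts.columns)
        return CountMatrix(out, self.samples.copy())

    def condition_mean(self, condition: str, time: int | None = None) -> pd.Series:
        """Per-region mean over replicate samples of one condition."""
        sel = {"condition": condition}
        if time is not None:
            sel["time"] = time
        sub = self.select(**sel)
        if sub.counts.shape[1] == 0:
            raise ValueError(f"condition {condition!r} (time={time}) absent")
        return sub.counts.mean(axis=1)
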