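"""Genomic bin tables and interval sets.

All coordinates are 0-based, half-open.  Bins tile each chromosome
contiguously at a fixed width; the last bin of a chromosome may be short.
Bin indices are genome-global (chromosome offsets applied in declaration
order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinTable", "IntervalSet", "read_bed", "write_bed"]


@dataclass(frozen=True)
class BinTable:
    """Fixed-width binning of a genome.

    Parameters
    ----------
    chrom_names : ordered chromosome labels.
    chrom_lengths : lengths in bp, same order.
    bin_width : bin width in bp.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    bin_width: int

    def __post_init__(self):
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_bins_per_chrom(self) -> np.ndarray:
        return np.array(
            [-(-l // self.bin_width) for l in self.chrom_lengths], dtype=int
        )

    @property
    def offsets(self) -> np.ndarray:
        """Genome-global index of the first bin of each chromosome, plus total."""
        return np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self.offsets[-1])

    @property
    def bin_chrom_ids(self) -> np.ndarray:
        """Per-bin chromosome index."""
        return np.repeat(np.arange(len(self.chrom_names)), self.n_bins_per_chrom)

    @property
    def bin_starts(self) -> np.ndarray:
        """Per-bin start coordinate (bp, within its chromosome)."""
        out = np.empty(self.n_bins, dtype=int)
        off = self.offsets
        for ci, n in enumerate(self.n_bins_per_chrom):
            out[off[ci] : off[ci + 1]] = np.arange(n) * self.bin_width
        return out

    @property
    def bin_ends(self) -> np.ndarray:
        ends = self.bin_starts + self.bin_width
        lens = np.asarray(self.chrom_lengths)[self.bin_chrom_ids]
        return np.minimum(ends, lens)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.chrom_index(chrom)
        off = self.offsets
        return slice(int(off[ci]), int(off[ci + 1]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Genome-global bin index containing ``pos`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.chrom_lengths[ci]})")
        return int(self.offsets[ci] + pos // self.bin_width)

    def region_slice(self, chrom: str, start: int | None = None, end: int | None = None) -> slice:
        """Slice of bins fully covering [start, end) on ``chrom``."""
        ci = self.chrom_index(chrom)
        off = int(self.offsets[ci])
        if start is None and end is None:
            return slice(off, int(self.offsets[ci + 1]))
        start = 0 if start is None else start
        end = self.chrom_lengths[ci] if end is None else min(end, self.chrom_lengths[ci])
        if start >= end:
            raise ValueError("empty region")
        lo = off + start // self.bin_width
        hi = off + -(-end // self.bin_width)
        return slice(int(lo), int(hi))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.chrom_names)[self.bin_chrom_ids],
                "start": self.bin_starts,
                "end": self.bin_ends,
            }
        )

    def __eq__(self, other):
        return (
            isinstance(other, BinTable)
            and self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_width == other.bin_width
        )

    def __hash__(self):
        return hash((self.chrom_names, self.chrom_lengths, self.bin_width))


@dataclass
class IntervalSet:
    """Labeled genomic intervals (peaks, rex sites), 0-based half-open."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires column {col!r}")
        df = df.reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.data = df

    def __len__(self):
        return len(self.data)

    def __iter__(self):
        return (row for _, row in self.data.iterrows())

    @classmethod
    def from_records(cls, records, columns=("chrom", "start", "end")):
        return cls(pd.DataFrame.from_records(list(records), columns=list(columns)))

    def midpoints(self) -> pd.DataFrame:
        mid = (self.data["start"] + self.data["end"]) // 2
        return pd.DataFrame({"chrom": self.data["chrom"], "pos": mid})

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (extra columns kept as name/score/strand)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.data.to_csv(path, sep="\t", header=False, index=False)
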