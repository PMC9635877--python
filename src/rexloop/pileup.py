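"""On-diagonal observed/expected meta-plots centered at anchor sets.

Averaging O/E submatrices across anchors (e.g. the strong rex sites) reveals
shared local structure — flames along the central row/column from anchored
one-sided extrusion, or focal corner peaks from stable loops — that is too
noisy to see at single loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bins import IntervalSet
from .contacts import ContactMap

__all__ = ["PileupResult", "on_diagonal_pileup"]


@dataclass
class PileupResult:
    matrix: np.ndarray     # (2f+1, 2f+1) mean O/E
    n_used: int
    n_dropped: int
    flank_bins: int


def on_diagonal_pileup(oe_map: ContactMap, anchors: IntervalSet, flank: int) -> PileupResult:
    """Mean O/E submatrix of half-width ``flank`` bp over anchor midpoints.

    Anchors whose flank extends past a chromosome end are dropped (count
    reported).  Missing pixels are excluded from the mean, not zero-filled.
    Anchor order does not affect the result.
    """
    bins = oe_map.bins
    f = flank // bins.bin_width
    size = 2 * f + 1
    sums = np.zeros((size, size))
    cnts = np.zeros((size, size), dtype=int)
    used = dropped = 0
    for row in anchors:
        chrom = row["chrom"]
        mid = (int(row["start"]) + int(row["end"])) // 2
        ci = bins.chrom_index(chrom)
        b = bins.bin_index(chrom, min(mid, bins.chrom_lengths[ci] - 1))
        sl = bins.chrom_slice(chrom)
        if b - f < sl.start or b + f + 1 > sl.stop:
            dropped += 1
            continue
        sub = oe_map.values[b - f : b + f + 1, b - f : b + f + 1]
        ok = np.isfinite(sub)
        sums[ok] += sub[ok]
        cnts += ok
        used += 1
    if used == 0:
        raise ValueError("no usable anchors (all dropped or empty set)")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return PileupResult(mean, used, dropped, f)
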