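"""Diamond insulation score and between-condition differencing.

The insulation score at bin i is the log2 of the mean balanced contact
frequency in the diamond window [i-w, i) x [i, i+w), normalized by the
chromosome-wide geometric mean of diamond means so that the non-missing
scores average zero per chromosome.  Dips mark contact insulation — TAD
boundaries and, in the dosage-compensation context, rex sites acting as
extrusion barriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactMap
from .tracks import ScalarTrack

__all__ = ["InsulationTrack", "insulation_score", "differential_insulation"]


@dataclass
class InsulationTrack(ScalarTrack):
    window: int = 0


def insulation_score(cmap: ContactMap, window: int) -> InsulationTrack:
    """Diamond insulation score with a window-bp arm on each side.

    Bins within ``window`` of a chromosome end, and bins whose diamond is
    fully missing, are NaN.  Scores are invariant to global rescaling of the
    balanced matrix.
    """
    bins = cmap.bins
    w = window // bins.bin_width
    if w < 3:
        raise ValueError("window must span at least 3 bins")
    n = bins.n_bins
    scores = np.full(n, np.nan)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        sub = cmap.values[sl, sl]
        m = sub.shape[0]
        diamond = np.full(m, np.nan)
        for i in range(w, m - w):
            block = sub[i - w : i, i : i + w]
            ok = np.isfinite(block)
            if ok.any():
                diamond[i] = block[ok].mean()
        pos = np.isfinite(diamond) & (diamond > 0)
        if pos.any():
            logd = np.full(m, np.nan)
            logd[pos] = np.log2(diamond[pos])
            logd[pos] -= logd[pos].mean()  # geometric-mean normalization
            scores[sl] = logd
    return InsulationTrack(bins, scores, {"window": window}, window=window)


def differential_insulation(track_a: InsulationTrack, track_b: InsulationTrack) -> ScalarTrack:
    """Per-bin difference a - b (e.g. insertion minus wild type remapped to
    the insertion genome); missing propagates."""
    if track_a.bins != track_b.bins:
        raise ValueError("tracks are on different bin tables")
    return ScalarTrack(track_a.bins, track_a.values - track_b.values, {"op": "difference"})
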