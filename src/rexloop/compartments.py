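"""A/B compartment eigenvector, saddle aggregation, and compartment strength.

EV1 is the leading eigenvector of the Pearson correlation matrix of the cis
observed/expected map over a region; its sign pattern separates the A and B
compartments and is oriented by positive correlation with a reference track
(gene density or active-chromatin coverage).  Saddle strength summarises the
checkerboard: bins are ranked by EV1 and split into quantiles, pixels are
pooled by quantile pair, and strength is the ratio of mean within-compartment
to mean across-compartment O/E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bins import BinTable
from .contacts import ContactMap, expected_by_distance, observed_over_expected
from .tracks import ScalarTrack

__all__ = [
    "EigenTrack",
    "SaddleResult",
    "compute_ev1",
    "saddle_strength",
    "local_strength_profile",
    "compare_conditions",
]


@dataclass
class EigenTrack:
    bins: BinTable
    values: np.ndarray          # NaN outside the region / invalid bins
    region: tuple               # (chrom, start, end)
    reference: str = ""

    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SaddleResult:
    matrix: np.ndarray          # k x k mean O/E by EV1 quantile
    strength: float
    k: int


def _region_oe(cmap: ContactMap, region, ignore_diags=None) -> tuple[np.ndarray, slice]:
    """O/E submatrix over one region, expected computed within the region."""
    chrom, start, end = region
    [prof] = expected_by_distance(cmap, {"region": [(chrom, start, end)]}, ignore_diags)
    oe = observed_over_expected(cmap, [prof])
    sl = cmap.bins.region_slice(chrom, start, end)
    return oe.values[sl, sl], sl


def _as_region(bins: BinTable, region) -> tuple:
    if isinstance(region, str):
        ci = bins.chrom_index(region)
        return (region, 0, bins.chrom_lengths[ci])
    chrom, start, end = region
    return (chrom, int(start), int(end))


def compute_ev1(
    cmap: ContactMap,
    region,
    reference_track: ScalarTrack | np.ndarray,
    ignore_diags: int | None = None,
) -> EigenTrack:
    """Leading eigenvector of the O/E correlation matrix over a region.

    The map must be balanced; O/E uses an expected profile computed within
    the region itself.  The eigenvector is unit-norm over valid bins and its
    sign is fixed so the correlation with the reference track is >= 0.
    """
    region = _as_region(cmap.bins, region)
    sub, sl = _region_oe(cmap, region, ignore_diags)
    m = sub.shape[0]
    valid = np.isfinite(sub).sum(axis=0) > max(2, m // 20)
    if valid.sum() < 10:
        raise ValueError("region has fewer than 10 valid bins")
    a = sub[np.ix_(valid, valid)]
    # fill residual missing pixels with the row/col mean so corrcoef is defined
    col_mean = np.nanmean(a, axis=0)
    fill = np.where(np.isnan(a), col_mean[None, :], a)
    fill = np.where(np.isnan(fill), 1.0, fill)
    corr = np.corrcoef(fill)
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    if not np.isfinite(evals).any() or np.allclose(corr, 0):
        raise ValueError("degenerate correlation matrix")
    v = evecs[:, -1]
    v = v / np.linalg.norm(v)

    ref = reference_track.values[sl] if isinstance(reference_track, ScalarTrack) else np.asarray(reference_track, float)[: m]
    ref = ref[valid]
    ok = np.isfinite(ref)
    if not ok.any():
        raise ValueError("reference track is all-missing over the region")
    if np.std(ref[ok]) > 0 and np.std(v[ok]) > 0:
        c = np.corrcoef(ref[ok], v[ok])[0, 1]
        if c < 0:
            v = -v

    out = np.full(cmap.bins.n_bins, np.nan)
    vals = np.full(m, np.nan)
    vals[valid] = v
    out[sl] = vals
    return EigenTrack(cmap.bins, out, region, getattr(reference_track, "meta", {}).get("name", "reference"))


def saddle_strength(
    oe_map: ContactMap,
    ev1: EigenTrack,
    k: int = 2,
    ignore_diags: int | None = None,
) -> SaddleResult:
    """Quantile-aggregated O/E and within/across compartment strength.

    Bins are ranked by EV1 and split into k equal-size quantiles (k=2: B and
    A halves).  Cell (p, q) is the mean O/E over cis pixel pairs in those
    quantiles, excluding the first ``ignore_diags`` diagonals.  Strength
    pools the diagonal (within) cells against the off-diagonal (across)
    cells: for k=2, mean(AA u BB) / mean(AB).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if ignore_diags is None:
        ignore_diags = max(int(oe_map.meta.get("ignore_diags", 0)), 1)
    valid = ev1.valid() & oe_map.valid_bins()
    idx = np.flatnonzero(valid)
    if len(idx) < k:
        raise ValueError(f"fewer valid bins ({len(idx)}) than quantiles ({k})")
    order = idx[np.argsort(ev1.values[idx], kind="stable")]
    groups = np.array_split(order, k)

    n = oe_map.n_bins
    qlab = np.full(n, -1)
    for g, members in enumerate(groups):
        qlab[members] = g
    cid = oe_map.bins.bin_chrom_ids
    sep_ok = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= ignore_diags
    cis = cid[:, None] == cid[None, :]
    pix_ok = np.isfinite(oe_map.values) & sep_ok & cis

    sums = np.zeros((k, k))
    cnts = np.zeros((k, k))
    for p in range(k):
        ip = qlab == p
        for q in range(k):
            iq = qlab == q
            m = pix_ok[np.ix_(ip, iq)]
            v = oe_map.values[np.ix_(ip, iq)]
            sums[p, q] = v[m].sum()
            cnts[p, q] = m.sum()
    with np.errstate(invalid="ignore"):
        saddle = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)

    within = np.eye(k, dtype=bool)
    sw, cw = sums[within].sum(), cnts[within].sum()
    sa, ca = sums[~within].sum(), cnts[~within].sum()
    if cw == 0 or ca == 0 or sa == 0:
        raise ValueError("insufficient pixels for strength")
    strength = (sw / cw) / (sa / ca)
    return SaddleResult(saddle, float(strength), k)


def local_strength_profile(
    cmap: ContactMap,
    reference_track,
    window: int,
    k: int = 2,
    min_valid_bins: int = 10,
    ignore_diags: int | None = None,
) -> ScalarTrack:
    """Compartment strength in non-overlapping window-sized tiles.

    For every tile, EV1 is recomputed on the tile's O/E submatrix (expected
    within the tile) and saddle strength is evaluated within the tile; tiles
    with fewer than ``min_valid_bins`` valid bins are missing.  Output is a
    track on a window-width bin table.
    """
    bins = cmap.bins
    if window < 20 * bins.bin_width:
        raise ValueError("window must span at least 20 bins")
    out_bins = BinTable(bins.chrom_names, bins.chrom_lengths, window)
    vals = np.full(out_bins.n_bins, np.nan)
    for ci, chrom in enumerate(bins.chrom_names):
        length = bins.chrom_lengths[ci]
        n_tiles = -(-length // window)
        for t in range(n_tiles):
            start, end = t * window, min((t + 1) * window, length)
            if end - start < 10 * bins.bin_width:
                continue
            try:
                ev = compute_ev1(cmap, (chrom, start, end), reference_track, ignore_diags)
            except ValueError:
                continue
            if ev.valid().sum() < min_valid_bins:
                continue
            [prof] = expected_by_distance(cmap, {"t": [(chrom, start, end)]}, ignore_diags)
            oe = observed_over_expected(cmap, [prof])
            try:
                res = saddle_strength(oe, ev, k, ignore_diags)
            except ValueError:
                continue
            vals[out_bins.bin_index(chrom, start)] = res.strength
    return ScalarTrack(out_bins, vals, {"window": window, "k": k})


def compare_conditions(track_a: ScalarTrack, track_b: ScalarTrack) -> ScalarTrack:
    """Elementwise ratio a/b of two tracks on the same tiling; missing
    propagates."""
    if track_a.bins != track_b.bins:
        raise ValueError("tracks are on different bin tables")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = track_a.values / track_b.values
        r = np.where(np.isfinite(r), r, np.nan)
    return ScalarTrack(track_a.bins, r, {"op": "ratio"})
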