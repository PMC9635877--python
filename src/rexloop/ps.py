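"""Contact-probability decay P(s), its log-derivative, and loop-size readout.

P(s) is the mean balanced contact frequency at genomic separation s, pooled
over log-spaced separation bins.  On a log-log plot, loop extrusion produces
a shoulder — a local flattening of the decay — whose position on the
log-derivative curve (the local maximum of d log P / d log s) is read as the
mean extruded loop size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .contacts import ContactMap

__all__ = ["PsProfile", "DerivativeProfile", "compute_ps", "log_derivative", "infer_loop_size"]

DEFAULT_LOG_BIN_FACTOR = 2 ** (1 / 8)


@dataclass
class PsProfile:
    region: str
    s: np.ndarray          # geometric bin centers, bp
    P: np.ndarray          # mean balanced contact frequency; NaN if no pixels
    n_pixels: np.ndarray   # valid pixels per log bin

    def valid(self) -> np.ndarray:
        return np.isfinite(self.P) & (self.n_pixels > 0)


@dataclass
class DerivativeProfile:
    s: np.ndarray
    slope: np.ndarray      # d log P / d log s
    smooth_sigma: float


def _per_separation_stats(cmap: ContactMap, regions, ignore_diags: int):
    """Pooled (sum, count) of valid balanced values per separation in bins."""
    bins = cmap.bins
    if regions is None:
        regions = list(bins.chrom_names)
    if isinstance(regions, (str, tuple)) and not isinstance(regions, list):
        regions = [regions]
    max_m = 0
    slices = []
    for r in regions:
        sl = bins.region_slice(r) if isinstance(r, str) else bins.region_slice(*r)
        if sl.stop - sl.start < 3:
            raise ValueError("region smaller than 3 bins")
        slices.append(sl)
        max_m = max(max_m, sl.stop - sl.start)
    sums = np.zeros(max_m)
    cnts = np.zeros(max_m, dtype=int)
    for sl in slices:
        sub = cmap.values[sl, sl]
        for d in range(max(1, ignore_diags), sub.shape[0]):
            diag = np.diagonal(sub, d)
            ok = np.isfinite(diag)
            sums[d] += diag[ok].sum()
            cnts[d] += int(ok.sum())
    return sums, cnts


def compute_ps(
    cmap: ContactMap,
    regions=None,
    log_bin_factor: float = DEFAULT_LOG_BIN_FACTOR,
    ignore_diags: int | None = None,
    region_label: str = "all",
) -> PsProfile:
    """Log-binned contact frequency versus separation.

    ``regions`` is a list of chromosome names and/or ``(chrom, start, end)``
    intervals; pixels with both ends in a region contribute, pooled across
    regions by pixel-weighted mean.  Separations are binned geometrically by
    ``log_bin_factor``; separations below ``ignore_diags`` (default taken
    from the map's balancing metadata) are excluded.
    """
    if log_bin_factor <= 1:
        raise ValueError("log_bin_factor must be > 1")
    if ignore_diags is None:
        ignore_diags = int(cmap.meta.get("ignore_diags", 0))
    sums, cnts = _per_separation_stats(cmap, regions, ignore_diags)
    bw = cmap.bins.bin_width
    max_sep = len(sums) - 1

    lo = max(1, ignore_diags)
    edges = [float(lo)]
    while edges[-1] <= max_sep:
        edges.append(max(edges[-1] * log_bin_factor, edges[-1] + 1))
    edges = np.array(edges)

    seps = np.arange(len(sums))
    which = np.digitize(seps, edges) - 1
    nb = len(edges) - 1
    P = np.full(nb, np.nan)
    s_centers = np.sqrt(edges[:-1] * edges[1:]) * bw
    n_pix = np.zeros(nb, dtype=int)
    sep_w = np.zeros(nb)
    for b in range(nb):
        sel = (which == b) & (seps >= lo)
        c = cnts[sel].sum()
        n_pix[b] = c
        if c > 0:
            P[b] = sums[sel].sum() / c
            # pixel-weighted mean separation as the reported s
            sep_w[b] = (seps[sel] * cnts[sel]).sum() / c
            s_centers[b] = sep_w[b] * bw
    keep = n_pix >= 0
    return PsProfile(region_label, s_centers[keep], P[keep], n_pix[keep])


def log_derivative(ps: PsProfile, smooth_sigma: float = 0.1) -> DerivativeProfile:
    """Slope of log10 P versus log10 s by central finite differences.

    ``smooth_sigma`` is the width (in log10(s) units) of a Gaussian kernel
    applied to log10 P before differencing; 0 disables smoothing.
    """
    ok = ps.valid() & (ps.P > 0) & (ps.s > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing P(s) points")
    ls = np.log10(ps.s[ok])
    lp = np.log10(ps.P[ok])
    if smooth_sigma > 0:
        # kernel-weighted local-linear smoothing: exact on pure power laws
        # (no edge bias from kernel truncation)
        w = np.exp(-((ls[:, None] - ls[None, :]) ** 2) / (2 * smooth_sigma**2))
        sw = w.sum(axis=1)
        swx = w @ ls
        swy = w @ lp
        swxx = w @ ls**2
        swxy = w @ (ls * lp)
        denom = sw * swxx - swx**2
        b = np.where(denom > 0, (sw * swxy - swx * swy) / np.where(denom > 0, denom, 1), 0.0)
        a = (swy - b * swx) / sw
        lp = a + b * ls
    slope = np.gradient(lp, ls)
    return DerivativeProfile(ps.s[ok], slope, smooth_sigma)


def infer_loop_size(deriv: DerivativeProfile, search_range=None):
    """Separation (bp) of the most prominent local maximum of the slope.

    Returns None when the slope curve is monotone within the search range
    (no shoulder — e.g. a pure power-law decay).  Ties in prominence break
    toward smaller s.
    """
    s = deriv.s
    slope = deriv.slope
    if search_range is not None:
        lo, hi = search_range
        sel = (s >= lo) & (s <= hi)
        if not sel.any():
            raise ValueError("empty search range")
        # keep one point of context on each side so edge peaks are detectable
        idx = np.flatnonzero(sel)
        a, b = max(idx[0] - 1, 0), min(idx[-1] + 2, len(s))
        s, slope = s[a:b], slope[a:b]
        inner = slice(idx[0] - a, idx[0] - a + len(idx))
    else:
        inner = slice(None)
    peaks, props = find_peaks(slope, prominence=0)
    if len(peaks) == 0:
        return None
    in_range = np.zeros(len(s), bool)
    in_range[inner] = True
    keep = in_range[peaks]
    peaks, prom = peaks[keep], props["prominences"][keep]
    if len(peaks) == 0:
        return None
    best = np.lexsort((s[peaks], -prom))[0]
    return float(s[peaks[best]])
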