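"""Per-bin signal tracks: ChIP normalization, X/A rescaling, peak consensus,
rex-site signal ratios, and domain-level expression aggregation.

The X/A rescaling addresses a technical property of dosage-compensation
ChIP-seq in C. elegans: the fraction of reads mapping to the X trades off
against the autosomes between experiments, so raw input-normalized signal is
not comparable across conditions.  Anchoring the autosomal mean (excluding
the experimentally manipulated chrII) at 0 and the chrX mean at 1 with the
affine transform xf = (xi - A) / (X - A) makes tracks cross-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinTable, IntervalSet

__all__ = [
    "ScalarTrack",
    "ChromGroupStats",
    "default_grouping",
    "ratio_track",
    "rescale_xa",
    "chrom_summary",
    "consensus_peaks",
    "rex_signal_ratio",
    "domain_expression_change",
    "domain_repression_pvalue",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class ScalarTrack:
    """Per-bin genomic signal; NaN marks missing bins."""

    bins: BinTable
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.bins.n_bins,):
            raise ValueError("track length does not match bin table")
        self.values = v

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bins.chrom_slice(chrom)]

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[self.bins.bin_index(chrom, pos)])

    def copy(self) -> "ScalarTrack":
        return ScalarTrack(self.bins, self.values.copy(), dict(self.meta))


@dataclass
class ChromGroupStats:
    """Group means used for X/A rescaling."""

    A: float  # mean over autosomes excluding chrII
    X: float  # mean over chrX


def default_grouping(bins: BinTable, x_name: str = "chrX", ii_name: str = "chrII") -> dict:
    """Chromosome -> group label in {autosome_nonII, chrII, chrX} by name."""
    grouping = {}
    for name in bins.chrom_names:
        key = name.removeprefix("chr")
        if name == x_name or key == "X":
            grouping[name] = "chrX"
        elif name == ii_name or key == "II":
            grouping[name] = "chrII"
        else:
            grouping[name] = "autosome_nonII"
    return grouping


def ratio_track(
    chip: ScalarTrack, control: ScalarTrack, pseudocount: float = 0.0, log2: bool = False
) -> ScalarTrack:
    """Input-normalized enrichment (chip+pc)/(control+pc), optionally log2."""
    if chip.bins != control.bins:
        raise ValueError("tracks are on different bin tables")
    a = chip.values + pseudocount
    b = control.values + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(np.isfinite(a) & np.isfinite(b) & (b > 0), a / b, np.nan)
        if log2:
            r = np.where(r > 0, np.log2(r), np.nan)
    return ScalarTrack(chip.bins, r, {"op": "ratio", "log2": log2})


def _group_masks(bins: BinTable, grouping: dict):
    cid = bins.bin_chrom_ids
    names = np.asarray(bins.chrom_names)
    labels = np.array([grouping.get(n, "autosome_nonII") for n in names])
    per_bin = labels[cid]
    return per_bin


def rescale_xa(track: ScalarTrack, grouping: dict | None = None):
    """Rescale so the autosomal (non-chrII) mean is 0 and the chrX mean is 1.

    Applies xf = (xi - A)/(X - A) per bin, where A and X are means of the
    valid bins in the respective chromosome groups.  Returns the rescaled
    track and the (A, X) statistics.
    """
    if grouping is None:
        grouping = default_grouping(track.bins)
    per_bin = _group_masks(track.bins, grouping)
    ok = np.isfinite(track.values)
    a_sel = (per_bin == "autosome_nonII") & ok
    x_sel = (per_bin == "chrX") & ok
    if not a_sel.any() or not x_sel.any():
        raise ValueError("empty autosome_nonII or chrX group")
    A = float(track.values[a_sel].mean())
    X = float(track.values[x_sel].mean())
    if X == A:
        raise ValueError("degenerate rescaling: X mean equals autosomal mean")
    xf = (track.values - A) / (X - A)
    return ScalarTrack(track.bins, xf, {"rescaled": True, "A": A, "X": X}), ChromGroupStats(A, X)


def chrom_summary(
    data,
    mode: str = "mean",
    grouping: dict | None = None,
    bins: BinTable | None = None,
    prescale: bool = False,
) -> pd.DataFrame:
    """Per-chromosome mean signal or peak count, affine-rescaled so the
    non-chrII autosomal mean is 0 and chrX is 1.

    ``data`` is a ScalarTrack (mode="mean") or an IntervalSet of peaks
    (mode="peak_count", with ``bins`` supplying the chromosome roster).
    ``prescale`` applies the per-bin X/A rescaling before summarizing.
    """
    if mode == "mean":
        track = data
        if prescale:
            track, _ = rescale_xa(track, grouping)
        bt = track.bins
        vals = {}
        for name in bt.chrom_names:
            v = track.chrom_values(name)
            v = v[np.isfinite(v)]
            vals[name] = v.mean() if len(v) else np.nan
    elif mode == "peak_count":
        if bins is None:
            raise ValueError("peak_count mode requires a bin table for the chromosome roster")
        bt = bins
        counts = data.data["chrom"].value_counts()
        vals = {name: float(counts.get(name, 0)) for name in bt.chrom_names}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if grouping is None:
        grouping = default_grouping(bt)
    auto = [vals[n] for n in bt.chrom_names if grouping.get(n) == "autosome_nonII"]
    xs = [vals[n] for n in bt.chrom_names if grouping.get(n) == "chrX"]
    if len(auto) < 2:
        raise ValueError("need at least 2 autosomes besides chrII")
    if not xs:
        raise ValueError("no chrX in grouping")
    A = float(np.nanmean(auto))
    X = float(np.nanmean(xs))
    if X == A:
        raise ValueError("degenerate rescaling: X mean equals autosomal mean")
    out = pd.DataFrame(
        {
            "chrom": list(bt.chrom_names),
            "group": [grouping.get(n) for n in bt.chrom_names],
            "value": [vals[n] for n in bt.chrom_names],
        }
    )
    out["rescaled"] = (out["value"] - A) / (X - A)
    return out


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


class _OverlapIndex:
    """Per-chromosome sorted-interval index for >=1 bp overlap queries."""

    def __init__(self, intervals: IntervalSet):
        self._idx = {}
        for chrom, grp in intervals.data.groupby("chrom"):
            order = np.argsort(grp["start"].to_numpy())
            starts = grp["start"].to_numpy()[order]
            ends = grp["end"].to_numpy()[order]
            self._idx[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom, start, end) -> bool:
        if chrom not in self._idx:
            return False
        starts, cummax_ends = self._idx[chrom]
        i = np.searchsorted(starts, end, side="left")
        return i > 0 and cummax_ends[i - 1] > start


def consensus_peaks(replicate_peaks, pooled_peaks: IntervalSet) -> IntervalSet:
    """Pooled peaks supported by a strict majority of replicate peak sets.

    A pooled peak is retained iff it overlaps (>= 1 bp) a peak in more than
    half of the replicate sets; with 2 replicates this means both.
    Coordinates come from the pooled set.
    """
    if len(replicate_peaks) < 1:
        raise ValueError("need at least one replicate set")
    if len(pooled_peaks) == 0:
        return IntervalSet(pooled_peaks.data)
    indexes = [_OverlapIndex(r) for r in replicate_peaks]
    need = len(replicate_peaks) / 2.0
    keep = []
    for i, row in pooled_peaks.data.iterrows():
        n = sum(ix.overlaps(row["chrom"], row["start"], row["end"]) for ix in indexes)
        keep.append(n > need)
    return IntervalSet(pooled_peaks.data[np.array(keep)])


def _window_mean(track: ScalarTrack, chrom: str, mid: int, width: int) -> float:
    ci = track.bins.chrom_index(chrom)
    lo, hi = mid - width // 2, mid + width // 2
    if lo < 0 or hi > track.bins.chrom_lengths[ci]:
        raise ValueError(f"{width}-bp window at {chrom}:{mid} truncated by chromosome end")
    sl = track.bins.region_slice(chrom, lo, hi)
    v = track.values[sl]
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    return float(v.mean())


def rex_signal_ratio(
    track: ScalarTrack, site, reference_sites: IntervalSet, width: int = 400
) -> float:
    """Signal in a width-bp window at a site, relative to the mean of the
    same statistic over reference sites (e.g. endogenous strong rex sites)."""
    chrom, start, end = site[0], int(site[1]), int(site[2])
    site_val = _window_mean(track, chrom, (start + end) // 2, width)
    refs = [
        _window_mean(track, row["chrom"], (row["start"] + row["end"]) // 2, width)
        for row in reference_sites
    ]
    ref_mean = float(np.nanmean(refs))
    return site_val / ref_mean


# ---------------------------------------------------------------------------
# Domain-level expression change
# ---------------------------------------------------------------------------


def domain_expression_change(genes: pd.DataFrame, bin_size: int, chrom_lengths: dict):
    """Mean per-gene log2 fold change within fixed genomic bins.

    Genes are assigned to bins by TSS.  Returns ``(track, chrom_means)``
    where the track is NaN for bins with no genes and ``chrom_means`` maps
    chromosome to its mean log2fc over genes.
    """
    if len(genes) == 0:
        raise ValueError("empty gene table")
    bt = BinTable(tuple(chrom_lengths), tuple(chrom_lengths.values()), bin_size)
    sums = np.zeros(bt.n_bins)
    cnts = np.zeros(bt.n_bins, dtype=int)
    for _, g in genes.iterrows():
        b = bt.bin_index(g["chrom"], int(g["tss"]))
        sums[b] += g["log2fc"]
        cnts[b] += 1
    vals = np.full(bt.n_bins, np.nan)
    nz = cnts > 0
    vals[nz] = sums[nz] / cnts[nz]
    chrom_means = {
        c: float(genes.loc[genes["chrom"] == c, "log2fc"].mean())
        for c in genes["chrom"].unique()
    }
    return ScalarTrack(bt, vals, {"bin_size": bin_size, "n_genes": len(genes)}), chrom_means


def domain_repression_pvalue(
    genes: pd.DataFrame, domain, n_perm: int = 10000, seed: int = 0
) -> float:
    """One-sided permutation p-value that genes in ``domain`` are repressed.

    ``domain`` is (chrom, start, end).  Gene log2fc labels are shuffled
    across all genes; p is the fraction of shuffles whose domain mean is at
    most the observed mean (repression = more negative).
    """
    chrom, start, end = domain
    inside = (
        (genes["chrom"] == chrom) & (genes["tss"] >= start) & (genes["tss"] < end)
    ).to_numpy()
    if inside.sum() == 0:
        raise ValueError("no genes in domain")
    fc = genes["log2fc"].to_numpy()
    obs = fc[inside].mean()
    rng = np.random.default_rng(seed)
    k = int(inside.sum())
    perm_means = np.array([rng.choice(fc, k, replace=False).mean() for _ in range(n_perm)])
    return float((np.sum(perm_means <= obs) + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------


def read_bedgraph(path, bins: BinTable) -> ScalarTrack:
    """Read a bedGraph onto a bin table (records must align to bins)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].astype(str).str.startswith("track")]
    vals = np.full(bins.n_bins, np.nan)
    for _, row in df.iterrows():
        sl = bins.region_slice(row["chrom"], int(row["start"]), int(row["end"]))
        vals[sl] = float(row["value"])
    return ScalarTrack(bins, vals)


def write_bedgraph(track: ScalarTrack, path, name: str | None = None) -> None:
    bt = track.bins
    df = bt.to_dataframe()
    df["value"] = track.values
    df = df[np.isfinite(track.values)]
    with open(path, "w") as fh:
        if name or track.meta:
            extras = " ".join(f"{k}={v}" for k, v in track.meta.items())
            fh.write(f"track type=bedGraph name={name or 'track'} {extras}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
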