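"""Contact-map data model, I/O, ICE balancing, expected/O-E, comparisons.

The :class:`ContactMap` holds a dense symmetric matrix of raw counts or
balanced contact frequencies with NaN marking missing pixels.  Maps at desk
scale (a few thousand bins) are kept dense; sparse inputs are densified on
read.

Balancing follows the iterative-correction convention: bins whose log10
marginal deviates from the per-chromosome median by more than ``mad_max``
median absolute deviations are masked, the first ``ignore_diags`` diagonals
are excluded from marginal sums, and the converged weights are rescaled so
that valid-bin marginals average one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .bins import BinTable

__all__ = [
    "ContactMap",
    "ExpectedProfile",
    "read_contacts",
    "write_contacts",
    "balance_ice",
    "expected_by_distance",
    "observed_over_expected",
    "log2_ratio_map",
    "remap_for_insertion",
    "remap_contact_map",
]


@dataclass
class ContactMap:
    """Binned symmetric contact matrix with per-bin balancing weights.

    ``values`` is dense (n_bins, n_bins); NaN marks missing pixels.
    ``weights`` is NaN for invalid bins.  ``meta`` records balancing
    parameters (``ignore_diags``, convergence diagnostics).
    """

    bins: BinTable
    values: np.ndarray
    weights: np.ndarray | None = None
    balanced: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.bins.n_bins
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match bin table ({n} bins)")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def valid_bins(self) -> np.ndarray:
        """Boolean mask of bins carrying data."""
        if self.weights is not None:
            return np.isfinite(self.weights)
        return ~np.all(np.isnan(self.values) | (self.values == 0), axis=0)

    def cis_mask(self) -> np.ndarray:
        cid = self.bins.bin_chrom_ids
        return cid[:, None] == cid[None, :]

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.bins,
            self.values.copy(),
            None if self.weights is None else self.weights.copy(),
            self.balanced,
            dict(self.meta),
        )


@dataclass
class ExpectedProfile:
    """Mean balanced contact frequency per separation (bins) within a group."""

    region_group: str
    values: np.ndarray  # indexed by separation in bins; NaN where undefined
    counts: np.ndarray
    regions: tuple = ()  # (chrom, start, end) regions the profile was computed on

    @property
    def chroms(self) -> tuple:
        return tuple(r[0] for r in self.regions)

    def at(self, sep: np.ndarray) -> np.ndarray:
        sep = np.asarray(sep)
        out = np.full(sep.shape, np.nan)
        ok = (sep >= 0) & (sep < len(self.values))
        out[ok] = self.values[sep[ok]]
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _densify(bins: BinTable, bin1, bin2, count) -> np.ndarray:
    n = bins.n_bins
    bin1 = np.asarray(bin1, dtype=int)
    bin2 = np.asarray(bin2, dtype=int)
    count = np.asarray(count, dtype=float)
    if len(bin1) and (bin1.min() < 0 or bin2.min() < 0 or bin1.max() >= n or bin2.max() >= n):
        raise ValueError(f"bin index out of range for a {n}-bin table")
    if len(count) and (count < 0).any():
        raise ValueError("negative contact count")
    m = np.zeros((n, n))
    np.add.at(m, (bin1, bin2), count)
    np.add.at(m, (bin2, bin1), count)
    # diagonal entries were added twice
    diag = bin1 == bin2
    if diag.any():
        np.add.at(m, (bin1[diag], bin2[diag]), -count[diag])
    return m


def read_contacts(path, fmt: str | None = None, bin_width: int | None = None) -> ContactMap:
    """Read a contact map from cool-style HDF5 or COO text.

    COO text has records ``bin1<TAB>bin2<TAB>count`` (upper triangle is
    enough; records are mirrored) and requires a sidecar ``<path>.chromsizes``
    file of ``chrom<TAB>length`` lines plus the bin width, given either as
    the ``bin_width`` argument or a ``# bin_width=<bp>`` header line.
    """
    path = str(path)
    if fmt is None:
        fmt = "cool" if path.endswith((".cool", ".h5", ".hdf5")) else "coo"
    if fmt == "cool":
        return _read_cool(path)
    if fmt == "coo":
        return _read_coo(path, bin_width)
    raise ValueError(f"unknown format {fmt!r}")


def _read_cool(path) -> ContactMap:
    with h5py.File(path, "r") as f:
        grp = f
        # single-resolution cooler layout at the file root
        names = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in grp["chroms/name"][:])
        lengths = tuple(int(x) for x in grp["chroms/length"][:])
        starts = grp["bins/start"][:]
        bw = int(grp.attrs.get("bin-size", 0)) or int(np.diff(starts[:2])[0]) if len(starts) > 1 else int(grp.attrs["bin-size"])
        bins = BinTable(names, lengths, bw)
        values = _densify(bins, grp["pixels/bin1_id"][:], grp["pixels/bin2_id"][:], grp["pixels/count"][:])
        weights = None
        balanced = False
        if "weight" in grp["bins"]:
            weights = grp["bins/weight"][:].astype(float)
            balanced = bool(grp.attrs.get("balanced", True))
            if balanced:
                w = weights
                values = values * w[:, None] * w[None, :]
        meta = {"ignore_diags": int(grp.attrs.get("ignore-diags", 0))}
    return ContactMap(bins, values, weights, balanced, meta)


def write_contacts(cmap: ContactMap, path, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "cool" if path.endswith((".cool", ".h5", ".hdf5")) else "coo"
    if fmt == "cool":
        _write_cool(cmap, path)
    elif fmt == "coo":
        _write_coo(cmap, path)
    elif fmt == "npz":
        np.savez(path, values=cmap.values,
                 weights=np.array([]) if cmap.weights is None else cmap.weights)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_cool(cmap: ContactMap, path) -> None:
    bins = cmap.bins
    if cmap.balanced and cmap.weights is not None:
        w = cmap.weights
        raw = cmap.values / (w[:, None] * w[None, :])
    else:
        raw = cmap.values
    iu = np.triu_indices(bins.n_bins)
    vals = raw[iu]
    keep = np.isfinite(vals) & (vals != 0)
    with h5py.File(path, "w") as f:
        f.attrs["bin-size"] = bins.bin_width
        f.attrs["balanced"] = cmap.balanced
        f.attrs["ignore-diags"] = cmap.meta.get("ignore_diags", 0)
        f.create_dataset("chroms/name", data=np.array(bins.chrom_names, dtype="S"))
        f.create_dataset("chroms/length", data=np.asarray(bins.chrom_lengths))
        f.create_dataset("bins/chrom", data=bins.bin_chrom_ids)
        f.create_dataset("bins/start", data=bins.bin_starts)
        f.create_dataset("bins/end", data=bins.bin_ends)
        if cmap.weights is not None:
            f.create_dataset("bins/weight", data=cmap.weights)
        f.create_dataset("pixels/bin1_id", data=iu[0][keep])
        f.create_dataset("pixels/bin2_id", data=iu[1][keep])
        f.create_dataset("pixels/count", data=vals[keep])


def _read_coo(path, bin_width) -> ContactMap:
    import pandas as pd

    chromsizes = pd.read_csv(str(path) + ".chromsizes", sep="\t", header=None, names=["chrom", "length"])
    bw = bin_width
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "bin_width=" in line:
                    bw = int(line.split("bin_width=")[1].strip())
            else:
                break
    if bw is None:
        raise ValueError("bin width not given and no '# bin_width=' header found")
    bins = BinTable(tuple(chromsizes["chrom"]), tuple(chromsizes["length"]), bw)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["bin1", "bin2", "count"])
    return ContactMap(bins, _densify(bins, df["bin1"], df["bin2"], df["count"]))


def _write_coo(cmap: ContactMap, path) -> None:
    bins = cmap.bins
    iu = np.triu_indices(bins.n_bins)
    vals = cmap.values[iu]
    keep = np.isfinite(vals) & (vals != 0)
    with open(path, "w") as fh:
        fh.write(f"# bin_width={bins.bin_width}\n")
        for b1, b2, c in zip(iu[0][keep], iu[1][keep], vals[keep]):
            fh.write(f"{b1}\t{b2}\t{c:g}\n")
    with open(str(path) + ".chromsizes", "w") as fh:
        for name, length in zip(bins.chrom_names, bins.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Balancing (iterative correction)
# ---------------------------------------------------------------------------


def _diag_exclusion_mask(bins: BinTable, ignore_diags: int) -> np.ndarray:
    """True for cis pixels within ignore_diags of the main diagonal."""
    n = bins.n_bins
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    cid = bins.bin_chrom_ids
    return (sep < ignore_diags) & (cid[:, None] == cid[None, :])


def balance_ice(
    cmap: ContactMap,
    max_iters: int = 500,
    mad_max: float = 5.0,
    ignore_diags: int = 2,
    tol: float = 1e-5,
) -> ContactMap:
    """Iteratively correct a raw contact map (matrix balancing).

    Returns a new :class:`ContactMap` with per-bin weights, balanced values
    ``w_i * w_j * raw_ij`` rescaled so valid-bin marginals average one, and
    invalid bins' rows/columns set to NaN.  The first ``ignore_diags``
    diagonals are excluded from marginal sums and blanked in the output.
    """
    if cmap.balanced:
        raw = cmap.values / (cmap.weights[:, None] * cmap.weights[None, :])
        raw = np.nan_to_num(raw)
    else:
        raw = np.nan_to_num(np.asarray(cmap.values, dtype=float))
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    n = cmap.n_bins
    excl = _diag_exclusion_mask(cmap.bins, ignore_diags)
    m_work = np.where(excl, 0.0, raw)

    coverage = m_work.sum(axis=0)
    valid = coverage > 0

    # MAD-max filter on log10 marginals vs per-chromosome median
    cid = cmap.bins.bin_chrom_ids
    for ci in range(len(cmap.bins.chrom_names)):
        sel = (cid == ci) & valid
        if not sel.any():
            continue
        logm = np.log10(coverage[sel])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        if mad > 0:
            bad = np.abs(logm - med) > mad_max * mad
            idx = np.flatnonzero(sel)[bad]
            valid[idx] = False

    if not valid.any():
        raise ValueError("no valid bins to balance")

    w = np.ones(n)
    w[~valid] = 0.0
    converged = False
    var = np.inf
    for it in range(max_iters):
        b = (m_work * w[:, None] * w[None, :]).sum(axis=0)
        mean_b = b[valid].mean()
        if mean_b == 0:
            raise ValueError("no valid bins to balance")
        rel = b[valid] / mean_b
        var = float(rel.var())
        if var < tol:
            converged = True
            break
        upd = np.ones(n)
        upd[valid] = rel
        w = w / upd

    if not converged:
        warnings.warn(
            f"balancing did not converge in {max_iters} iterations (marginal variance {var:.3g})",
            RuntimeWarning,
        )

    # rescale so valid marginals average 1
    b = (m_work * w[:, None] * w[None, :]).sum(axis=0)
    scale = b[valid].mean()
    w = w / np.sqrt(scale)
    w_out = np.where(valid, w, np.nan)

    balanced = raw * w_out[:, None] * w_out[None, :]
    balanced[excl] = np.nan
    meta = dict(cmap.meta)
    meta.update(
        ignore_diags=ignore_diags,
        balance_converged=converged,
        balance_iters=it + 1,
        balance_marginal_var=var,
    )
    return ContactMap(cmap.bins, balanced, w_out, True, meta)


# ---------------------------------------------------------------------------
# Expected / observed-over-expected
# ---------------------------------------------------------------------------


def _normalize_groups(bins: BinTable, region_groups) -> dict:
    """Map group label -> list of (chrom, start, end) regions."""
    out = {}
    for label, regions in region_groups.items():
        regs = []
        if isinstance(regions, str):
            regions = [regions]
        for r in regions:
            if isinstance(r, str):
                ci = bins.chrom_index(r)
                regs.append((r, 0, bins.chrom_lengths[ci]))
            else:
                chrom, start, end = r
                regs.append((chrom, int(start), int(end)))
        if not regs:
            raise ValueError(f"empty region group {label!r}")
        out[label] = regs
    return out


def expected_by_distance(cmap: ContactMap, region_groups, ignore_diags: int | None = None):
    """Per-group mean balanced contact frequency at each separation (bins).

    ``region_groups`` maps a label to chromosome names or (chrom, start, end)
    regions; cis pixels with both ends inside a region contribute.
    """
    if ignore_diags is None:
        ignore_diags = int(cmap.meta.get("ignore_diags", 0))
    groups = _normalize_groups(cmap.bins, region_groups)
    profiles = []
    for label, regs in groups.items():
        max_len = max(cmap.bins.region_slice(*r).stop - cmap.bins.region_slice(*r).start for r in regs)
        sums = np.zeros(max_len)
        cnts = np.zeros(max_len)
        for r in regs:
            sl = cmap.bins.region_slice(*r)
            sub = cmap.values[sl, sl]
            m = sub.shape[0]
            for d in range(ignore_diags, m):
                diag = np.diagonal(sub, d)
                ok = np.isfinite(diag)
                sums[d] += diag[ok].sum()
                cnts[d] += ok.sum()
        vals = np.full(max_len, np.nan)
        nz = cnts > 0
        vals[nz] = sums[nz] / cnts[nz]
        vals[:ignore_diags] = np.nan
        profiles.append(ExpectedProfile(label, vals, cnts, tuple(regs)))
    return profiles


def observed_over_expected(cmap: ContactMap, expected) -> ContactMap:
    """Divide each cis pixel by its group's distance-expected value.

    ``expected`` is the list returned by :func:`expected_by_distance`; each
    chromosome of the map must be covered by exactly one profile's regions.
    Pixels outside all groups, trans pixels, and separations with missing
    expected become NaN.
    """
    if isinstance(expected, ExpectedProfile):
        expected = [expected]
    n = cmap.n_bins
    oe = np.full((n, n), np.nan)
    for prof in expected:
        for chrom, start, end in prof.regions:
            sl = cmap.bins.region_slice(chrom, start, end)
            sub = cmap.values[sl, sl]
            m = sub.shape[0]
            sep = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
            exp = prof.at(sep)
            with np.errstate(divide="ignore", invalid="ignore"):
                res = np.where(np.isfinite(exp) & (exp > 0), sub / exp, np.nan)
            oe[sl, sl] = res
    meta = dict(cmap.meta)
    meta["oe"] = True
    return ContactMap(cmap.bins, oe, cmap.weights, cmap.balanced, meta)


# ---------------------------------------------------------------------------
# Map comparison and insertion-genome remapping
# ---------------------------------------------------------------------------


def log2_ratio_map(map_a: ContactMap, map_b: ContactMap, pseudocount: float = 0.0) -> np.ndarray:
    """Per-pixel log2((a+pc)/(b+pc)); NaN where either side is missing or
    non-positive after the pseudocount."""
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("contact maps have different shapes")
    a = map_a.values + pseudocount
    b = map_b.values + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((a > 0) & (b > 0), np.log2(a) - np.log2(b), np.nan)
    return out


def remap_for_insertion(bins_wt: BinTable, insertion):
    """Bin table and index mapping for a genome with an insertion.

    ``insertion`` is ``(chrom, position_bp, length_bp)`` or a list of such
    (non-overlapping, any order).  The inserted length is carried as whole
    bins (``ceil(length/bin_width)``) so that existing bin boundaries are
    preserved.  Returns ``(new_bins, mapping)`` where ``mapping[i]`` is the
    new genome-global index of old bin ``i``; inserted bins carry no
    wild-type data.
    """
    if isinstance(insertion, tuple):
        insertions = [insertion]
    else:
        insertions = list(insertion)
    bw = bins_wt.bin_width
    per_chrom = {}
    for chrom, pos, length in insertions:
        ci = bins_wt.chrom_index(chrom)
        if length < 0:
            raise ValueError("insertion length must be >= 0")
        if not 0 <= pos <= bins_wt.chrom_lengths[ci]:
            raise ValueError(f"insertion position {pos} beyond {chrom} end")
        per_chrom.setdefault(chrom, []).append((pos, -(-length // bw)))

    new_lengths = list(bins_wt.chrom_lengths)
    mapping = np.arange(bins_wt.n_bins)
    for chrom, ins_list in per_chrom.items():
        ci = bins_wt.chrom_index(chrom)
        sl = bins_wt.chrom_slice(chrom)
        shift = np.zeros(sl.stop - sl.start, dtype=int)
        total_extra = 0
        for pos, extra in ins_list:
            k = pos // bw  # bin-in-chrom at which new bins appear
            shift[k:] += extra
            total_extra += extra
        mapping[sl] += shift
        new_lengths[ci] += total_extra * bw
    # shift for preceding chromosomes' growth
    extra_per_chrom = np.zeros(len(bins_wt.chrom_names), dtype=int)
    for chrom, ins_list in per_chrom.items():
        extra_per_chrom[bins_wt.chrom_index(chrom)] = sum(e for _, e in ins_list)
    chrom_shift = np.concatenate([[0], np.cumsum(extra_per_chrom)])[:-1]
    mapping += chrom_shift[bins_wt.bin_chrom_ids]

    new_bins = BinTable(bins_wt.chrom_names, tuple(new_lengths), bw)
    return new_bins, mapping


def remap_contact_map(cmap: ContactMap, new_bins: BinTable, mapping: np.ndarray) -> ContactMap:
    """Lift a wild-type map onto an insertion genome; inserted bins are NaN."""
    n_new = new_bins.n_bins
    vals = np.full((n_new, n_new), np.nan)
    vals[np.ix_(mapping, mapping)] = cmap.values
    weights = None
    if cmap.weights is not None:
        weights = np.full(n_new, np.nan)
        weights[mapping] = cmap.weights
    return ContactMap(new_bins, vals, weights, cmap.balanced, dict(cmap.meta))
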