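import numpy as np
import pytest

import rexloop as rl
from rexloop.contacts import _densify


def ipf_oracle(m, ignore_diags=0, iters=2000):
    """Independent iterative-proportional-fitting: alternately divide rows
    and columns by their marginals until the matrix is doubly stochastic
    (up to scale).  Returns the balanced matrix."""
    x = m.astype(float).copy()
    n = x.shape[0]
    excl = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) < ignore_diags
    work = np.where(excl, 0.0, x)
    b = np.ones(n)
    for _ in range(iters):
        s = (work * b[:, None] * b[None, :]).sum(axis=0)
        s = s / s[s > 0].mean()
        b = np.where(s > 0, b / s, b)
    out = x * b[:, None] * b[None, :]
    s = (np.where(excl, 0, out)).sum(axis=0)
    return out / s[s > 0].mean()


class TestIO:
    def test_cool_round_trip(self, tmp_path):
        bins = rl.BinTable(("chr1",), (100_000,), 10_000)
        rng = np.random.default_rng(0)
        m = rng.integers(0, 20, (10, 10)).astype(float)
        m = m + m.T
        cmap = rl.ContactMap(bins, m)
        p = tmp_path / "t.cool"
        rl.write_contacts(cmap, p)
        back = rl.read_contacts(p)
        assert back.bins == bins
        np.testing.assert_allclose(back.values, m)

    def test_coo_round_trip_with_chromsizes_sidecar(self, tmp_path):
        bins = rl.BinTable(("chr1", "chr2"), (30_000, 20_000), 10_000)
        m = np.zeros((5, 5))
        m[0, 1] = m[1, 0] = 4
        m[3, 4] = m[4, 3] = 2
        m[2, 2] = 7
        p = tmp_path / "t.coo"
        rl.write_contacts(rl.ContactMap(bins, m), p)
        back = rl.read_contacts(p)
        assert back.bins == bins
        np.testing.assert_allclose(back.values, m)

    def test_coo_records_are_mirrored(self):
        bins = rl.BinTable(("c",), (30_000,), 10_000)
        m = _densify(bins, [0, 1], [1, 2], [4, 2])
        expect = np.array([[0, 4, 0], [4, 0, 2], [0, 2, 0]], dtype=float)
        np.testing.assert_array_equal(m, expect)

    def test_out_of_range_bin_rejected(self):
        bins = rl.BinTable(("c",), (100_000,), 10_000)
        with pytest.raises(ValueError, match="out of range"):
            _densify(bins, [0], [99], [1])

    def test_negative_count_rejected(self):
        bins = rl.BinTable(("c",), (30_000,), 10_000)
        with pytest.raises(ValueError, match="negative"):
            _densify(bins, [0], [1], [-3])


class TestBalance:
    def test_symmetric_2x2_already_balanced(self):
        bins = rl.BinTable(("c",), (20_000,), 10_000)
        cmap = rl.ContactMap(bins, np.array([[0.0, 1.0], [1.0, 0.0]]))
        out = rl.balance_ice(cmap, ignore_diags=0)
        assert np.isfinite(out.weights).all()
        np.testing.assert_allclose(out.weights[0], out.weights[1])
        marg = np.nansum(out.values, axis=0)
        np.testing.assert_allclose(marg, [1.0, 1.0], atol=1e-6)

    def test_matches_ipf_oracle_and_marginal_cv(self):
        rng = np.random.default_rng(3)
        bins = rl.BinTable(("c",), (40_000,), 10_000)
        m = rng.uniform(1, 10, (4, 4))
        m = m + m.T
        out = rl.balance_ice(rl.ContactMap(bins, m), ignore_diags=0, tol=1e-14)
        oracle = ipf_oracle(m)
        np.testing.assert_allclose(out.values, oracle, rtol=1e-6)
        marg = np.nansum(out.values, axis=0)
        assert marg.std() / marg.mean() < 1e-4

    def test_zero_coverage_bin_invalidated(self, random_count_map):
        out = rl.balance_ice(random_count_map)
        assert np.isnan(out.weights[12])
        assert np.isnan(out.values[12, :]).all()
        assert np.isnan(out.values[:, 12]).all()

    def test_idempotence(self, random_count_map):
        once = rl.balance_ice(random_count_map, tol=1e-12)
        twice = rl.balance_ice(once, tol=1e-12)
        ok = np.isfinite(once.weights)
        np.testing.assert_allclose(twice.weights[ok], once.weights[ok], rtol=1e-6)

    def test_ignore_diags_excluded_from_output(self, random_count_map):
        out = rl.balance_ice(random_count_map, ignore_diags=2)
        cid = out.bins.bin_chrom_ids
        for i in range(out.n_bins - 1):
            if cid[i] == cid[i + 1]:
                assert np.isnan(out.values[i, i + 1])

    def test_no_valid_bins_raises(self):
        bins = rl.BinTable(("c",), (30_000,), 10_000)
        with pytest.raises(ValueError, match="no valid bins"):
            rl.balance_ice(rl.ContactMap(bins, np.zeros((3, 3))))

    def test_nonconvergence_warns_and_flags(self, random_count_map):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            out = rl.balance_ice(random_count_map, max_iters=1, tol=1e-16)
        assert out.meta["balance_converged"] is False


class TestExpected:
    def _balanced(self, values, chroms=("c",), lengths=None, bw=10_000):
        n = values.shape[0]
        lengths = lengths or (n * bw,)
        bins = rl.BinTable(chroms, lengths, bw)
        return rl.ContactMap(bins, values, np.ones(n), True, {"ignore_diags": 0})

    def test_constant_map_flat_expected(self):
        cmap = self._balanced(np.full((6, 6), 3.0))
        [prof] = rl.expected_by_distance(cmap, {"g": ["c"]})
        np.testing.assert_allclose(prof.values, 3.0)

    def test_value_equals_separation(self):
        n = 5
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        cmap = self._balanced(sep)
        [prof] = rl.expected_by_distance(cmap, {"g": ["c"]})
        np.testing.assert_allclose(prof.values, np.arange(n))

    def test_group_separation_normalizes_each_group(self):
        # chrom B values are 2x chrom A at every separation; per-group O/E = 1
        bw = 10_000
        bins = rl.BinTable(("A", "B"), (50_000, 50_000), bw)
        n = bins.n_bins
        vals = np.full((n, n), np.nan)
        sepA = np.abs(np.subtract.outer(np.arange(5), np.arange(5))) + 1.0
        vals[:5, :5] = 1.0 / sepA
        vals[5:, 5:] = 2.0 / sepA
        cmap = rl.ContactMap(bins, vals, np.ones(n), True, {"ignore_diags": 0})
        profs = rl.expected_by_distance(cmap, {"a": ["A"], "b": ["B"]})
        oe = rl.observed_over_expected(cmap, profs)
        for sl in (slice(0, 5), slice(5, 10)):
            sub = oe.values[sl, sl]
            for d in range(5):
                diag = np.diagonal(sub, d)
                np.testing.assert_allclose(diag[np.isfinite(diag)], 1.0)

    def test_empty_group_raises(self):
        cmap = self._balanced(np.ones((4, 4)))
        with pytest.raises(ValueError, match="empty region group"):
            rl.expected_by_distance(cmap, {"g": []})


class TestObservedOverExpected:
    def test_self_normalization_per_distance_means_one(self, random_count_map):
        balanced = rl.balance_ice(random_count_map)
        groups = {"A": ["chrA"], "B": ["chrB"]}
        profs = rl.expected_by_distance(balanced, groups)
        oe = rl.observed_over_expected(balanced, profs)
        for chrom in ("chrA", "chrB"):
            sl = balanced.bins.chrom_slice(chrom)
            sub = oe.values[sl, sl]
            for d in range(2, sub.shape[0]):
                diag = np.diagonal(sub, d)
                vals = diag[np.isfinite(diag)]
                if len(vals):
                    np.testing.assert_allclose(vals.mean(), 1.0, atol=1e-9)

    def test_single_elevated_pixel(self):
        n = 6
        vals = np.ones((n, n))
        vals[1, 4] = vals[4, 1] = 4.0
        bins = rl.BinTable(("c",), (n * 10_000,), 10_000)
        cmap = rl.ContactMap(bins, vals, np.ones(n), True, {"ignore_diags": 0})
        [prof] = rl.expected_by_distance(cmap, {"g": ["c"]})
        oe = rl.observed_over_expected(cmap, [prof])
        above = np.argwhere(oe.values > 1.0)
        assert {tuple(x) for x in above} == {(1, 4), (4, 1)}

    def test_missing_expected_propagates(self):
        n = 5
        bins = rl.BinTable(("c",), (n * 10_000,), 10_000)
        cmap = rl.ContactMap(bins, np.ones((n, n)), np.ones(n), True, {"ignore_diags": 0})
        [prof] = rl.expected_by_distance(cmap, {"g": ["c"]})
        prof.values[3] = np.nan
        oe = rl.observed_over_expected(cmap, [prof])
        for i in range(n - 3):
            assert np.isnan(oe.values[i, i + 3])


class TestLog2Ratio:
    def _map(self, vals):
        n = vals.shape[0]
        bins = rl.BinTable(("c",), (n * 10_000,), 10_000)
        return rl.ContactMap(bins, vals, np.ones(n), True)

    def test_identity_is_zero(self):
        a = self._map(np.ones((4, 4)) * 3)
        np.testing.assert_array_equal(rl.log2_ratio_map(a, a), np.zeros((4, 4)))

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(1)
        a = self._map(rng.uniform(0.5, 2, (5, 5)))
        b = self._map(rng.uniform(0.5, 2, (5, 5)))
        np.testing.assert_array_equal(
            rl.log2_ratio_map(a, b), -rl.log2_ratio_map(b, a)
        )

    def test_hand_value(self):
        a = self._map(np.full((3, 3), 4.0))
        b = self._map(np.full((3, 3), 1.0))
        np.testing.assert_allclose(rl.log2_ratio_map(a, b, pseudocount=0), 2.0)

    def test_shape_mismatch_raises(self):
        a = self._map(np.ones((3, 3)))
        b = self._map(np.ones((4, 4)))
        with pytest.raises(ValueError):
            rl.log2_ratio_map(a, b)


class TestInsertionRemap:
    def test_zero_length_identity(self):
        bins = rl.BinTable(("c",), (100_000,), 10_000)
        new_bins, mapping = rl.remap_for_insertion(bins, ("c", 50_000, 0))
        assert new_bins == bins
        np.testing.assert_array_equal(mapping, np.arange(10))

    def test_two_bin_insertion_shifts_downstream(self):
        bins = rl.BinTable(("c",), (100_000,), 10_000)
        new_bins, mapping = rl.remap_for_insertion(bins, ("c", 50_000, 20_000))
        assert new_bins.n_bins == 12
        np.testing.assert_array_equal(mapping[:5], np.arange(5))
        np.testing.assert_array_equal(mapping[5:], np.arange(5, 10) + 2)

    def test_position_beyond_end_raises(self):
        bins = rl.BinTable(("c",), (100_000,), 10_000)
        with pytest.raises(ValueError, match="beyond"):
            rl.remap_for_insertion(bins, ("c", 150_000, 10_000))

    def test_composition_equals_combined(self):
        bins = rl.BinTable(("c",), (200_000,), 10_000)
        # two non-overlapping insertions applied jointly
        joint_bins, joint_map = rl.remap_for_insertion(
            bins, [("c", 30_000, 10_000), ("c", 120_000, 20_000)]
        )
        # sequential: first at 120k, then at 30k (upstream unaffected)
        b1, m1 = rl.remap_for_insertion(bins, ("c", 120_000, 20_000))
        b2, m2 = rl.remap_for_insertion(b1, ("c", 30_000, 10_000))
        np.testing.assert_array_equal(m2[m1], joint_map)
        assert b2 == joint_bins

    def test_remap_contact_map_inserted_bins_missing(self):
        bins = rl.BinTable(("c",), (50_000,), 10_000)
        vals = np.arange(25, dtype=float).reshape(5, 5)
        vals = (vals + vals.T) / 2
        cmap = rl.ContactMap(bins, vals, np.ones(5), True)
        new_bins, mapping = rl.remap_for_insertion(bins, ("c", 20_000, 10_000))
        out = rl.remap_contact_map(cmap, new_bins, mapping)
        assert out.n_bins == 6
        assert np.isnan(out.values[2, :]).all()
        np.testing.assert_allclose(out.values[np.ix_(mapping, mapping)], vals)
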