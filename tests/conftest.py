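import numpy as np
import pytest

import rexloop as rl


@pytest.fixture
def small_bins():
    return rl.BinTable(("chrA", "chrB"), (100_000, 60_000), 10_000)  # 10 + 6 bins


@pytest.fixture
def random_count_map(small_bins):
    """Symmetric random positive counts, one zero-coverage bin (index 12)."""
    rng = np.random.default_rng(42)
    n = small_bins.n_bins
    m = rng.integers(1, 50, size=(n, n)).astype(float)
    m = m + m.T
    m[12, :] = 0.0
    m[:, 12] = 0.0
    return rl.ContactMap(small_bins, m)


@pytest.fixture(scope="session")
def barrier_ensembles():
    """One chromosome with a central rex barrier, uniform one-sided loading,
    simulated over p_stall grid x 3 seeds.  Shared by insulation tests."""
    bw = 10_000
    out = {}
    for p_stall in (0.0, 0.3, 0.7, 1.0):
        for seed in (1, 2, 3):
            rex = [("chrS", 2_000_000, 1.0, p_stall)] if p_stall > 0 else []
            genome = rl.build_sim_genome({"chrS": 4_000_000}, bw, rex)
            cfg = rl.LefConfig(
                n_lefs=20, k_off=0.03, v=1.0, D=0.1, mode="one_sided_uniform",
                burn_in=400, n_samples=160, sample_interval=8, seed=seed,
            )
            out[(p_stall, seed)] = rl.simulate_lefs(genome, cfg)
    return out


@pytest.fixture(scope="session")
def barrier_maps(barrier_ensembles):
    return {key: rl.loops_to_contact_map(ens) for key, ens in barrier_ensembles.items()}


@pytest.fixture(scope="session")
def x_like_runs():
    """Flagship X-like simulations (rex loading + barriers, realized mean
    loop ~20 bins) for 3 seeds: (ensemble, contact map) each."""
    from rexloop import scenarios as sc

    runs = {}
    genome = sc.x_like_genome()
    for seed in (1, 2, 3):
        ens = rl.simulate_lefs(genome, sc.x_like_config(seed))
        runs[seed] = (ens, rl.loops_to_contact_map(ens))
    return runs


@pytest.fixture(scope="session")
def mirrored_barrier_insulation():
    """Insulation at the rex bin for the p_stall=0.7 barrier scenario run on
    the mirrored genome, 3 seeds."""
    from rexloop import scenarios as sc

    out = []
    genome = sc.barrier_genome(0.7).mirrored()
    b_mirror = genome.chrom_lengths_bins[0] - 1 - sc.BARRIER_BIN
    for seed in (1, 2, 3):
        ens = rl.simulate_lefs(genome, sc.barrier_config(seed))
        track = rl.insulation_score(rl.loops_to_contact_map(ens), 200_000)
        out.append(track.values[b_mirror])
    return np.array(out)


@pytest.fixture(scope="session")
def point_site_oe_maps():
    """O/E maps for one- vs two-sided loading at a single point site."""
    from rexloop import scenarios as sc

    genome = sc.point_site_genome()
    out = {}
    for mode in ("one_sided_rex_loading", "two_sided_point"):
        for seed in (1, 2):
            ens = rl.simulate_lefs(genome, sc.point_site_config(mode, seed))
            m = rl.loops_to_contact_map(ens)
            exp = rl.expected_by_distance(m, {"chrS": ["chrS"]})
            out[(mode, seed)] = rl.observed_over_expected(m, exp)
    return out
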