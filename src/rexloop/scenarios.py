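"""Frozen synthetic study conditions used by the benchmark suite.

Each scenario fixes a genome, rex layout and LEF kinetics emulating one
facet of condensin-DC biology at desk scale, so that analyses run on the
generated maps are comparable across the test suite and the reproduction
script.  Sizes follow the X chromosome scaled down: 10-kb bins, chromosomes
of 3-10 Mb, loop sizes of ~200 kb.

Scenario rationale:

* ``x_like`` — a 10-Mb "X" (1,000 bins) tiled with rex sites every 300 kb
  (loading + 0.7 barrier), 24 LEFs with unloading tuned so the realized mean
  loop is ~20 bins = 200 kb.  Used for P(s)/loop-size and shoulder analyses.
* ``barrier`` — a 4-Mb chromosome with uniform one-sided loading and a single
  central rex whose stall probability is varied; isolates barrier-driven
  insulation from loading effects.
* ``point_site`` — a 3-Mb chromosome with a single loading site and no
  barrier, run in one-sided or two-sided mode; generates the flame vs
  anti-diagonal signature pair.
* ``repression`` — a 5-Mb chromosome with rex sites confined to the central
  1.5 Mb, so LEF occupancy (and hence simulated repression) is domain-
  restricted.
"""

from __future__ import annotations

import numpy as np

from .sim import LefConfig, SimGenome, build_sim_genome

__all__ = [
    "BIN_WIDTH",
    "x_like_genome",
    "x_like_config",
    "X_LIKE_REX_BINS",
    "barrier_genome",
    "barrier_config",
    "BARRIER_BIN",
    "point_site_genome",
    "point_site_config",
    "POINT_SITE_BIN",
    "repression_genome",
    "repression_config",
    "REPRESSION_DOMAIN",
]

BIN_WIDTH = 10_000

# --- X-like chromosome: rex every 300 kb --------------------------------

X_LIKE_REX_BINS = tuple(range(15, 990, 30))


def x_like_genome() -> SimGenome:
    rex = [("chrX", b * BIN_WIDTH + BIN_WIDTH // 2, 1.0, 0.7) for b in X_LIKE_REX_BINS]
    return build_sim_genome({"chrX": 10_000_000}, BIN_WIDTH, rex)


def x_like_config(seed: int, n_samples: int = 250) -> LefConfig:
    # k_off tuned so the realized mean loop is ~20 bins (200 kb) at this density
    return LefConfig(
        n_lefs=24, k_off=0.018, v=1.0, D=0.1, mode="one_sided_rex_loading",
        burn_in=500, n_samples=n_samples, sample_interval=8, seed=seed,
    )


# --- single central barrier, uniform loading ----------------------------

BARRIER_BIN = 200


def barrier_genome(p_stall: float) -> SimGenome:
    rex = [("chrS", BARRIER_BIN * BIN_WIDTH, 1.0, p_stall)] if p_stall > 0 else []
    return build_sim_genome({"chrS": 4_000_000}, BIN_WIDTH, rex)


def barrier_config(seed: int, n_samples: int = 160) -> LefConfig:
    return LefConfig(
        n_lefs=20, k_off=0.03, v=1.0, D=0.1, mode="one_sided_uniform",
        burn_in=400, n_samples=n_samples, sample_interval=8, seed=seed,
    )


# --- single point loading site (signature dichotomy) --------------------

POINT_SITE_BIN = 150


def point_site_genome() -> SimGenome:
    return build_sim_genome(
        {"chrS": 3_000_000}, BIN_WIDTH, [("chrS", POINT_SITE_BIN * BIN_WIDTH, 1.0, 0.0)]
    )


def point_site_config(mode: str, seed: int, n_samples: int = 200) -> LefConfig:
    return LefConfig(
        n_lefs=3, k_off=0.02, v=1.0, D=0.1, mode=mode,
        burn_in=400, n_samples=n_samples, sample_interval=8, seed=seed,
    )


# --- domain-restricted occupancy for expression coupling ----------------

REPRESSION_DOMAIN = ("chrS", 1_750_000, 3_250_000)


def repression_genome() -> SimGenome:
    rex_pos = np.arange(1_900_000, 3_200_000, 300_000)
    rex = [("chrS", int(p), 1.0, 0.7) for p in rex_pos]
    return build_sim_genome({"chrS": 5_000_000}, BIN_WIDTH, rex)


def repression_config(seed: int, n_samples: int = 150) -> LefConfig:
    return LefConfig(
        n_lefs=20, k_off=0.032, v=1.0, D=0.1, mode="one_sided_rex_loading",
        burn_in=400, n_samples=n_samples, sample_interval=8, seed=seed,
    )


def checkerboard_map(n_bins: int = 400, block: int = 25, contrast: float = 0.3,
                     alpha: float = 1.0, d0: float = 1.0):
    """Synthetic compartment checkerboard: power-law decay modulated by
    alternating A/B blocks, (|i-j|+d0)^(-alpha) * (1 + contrast*s_i*s_j).

    Returns (ContactMap, sign_track) where sign_track is the generating
    A/B label per bin (+1/-1), usable as an EV1 orientation reference.
    """
    from .bins import BinTable
    from .contacts import ContactMap
    from .tracks import ScalarTrack

    bins = BinTable(("chrS",), (n_bins * BIN_WIDTH,), BIN_WIDTH)
    sign = np.where((np.arange(n_bins) // block) % 2 == 0, 1.0, -1.0)
    grid = np.arange(n_bins)
    bg = (np.abs(grid[:, None] - grid[None, :]) + d0) ** (-alpha)
    vals = bg * (1 + contrast * sign[:, None] * sign[None, :])
    cmap = ContactMap(bins, vals, np.ones(n_bins), balanced=True, meta={"ignore_diags": 0})
    return cmap, ScalarTrack(bins, sign)
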