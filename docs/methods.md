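# Methods

## Coordinate conventions

All coordinates are 0-based, half-open. Bins tile each chromosome
contiguously at a fixed width; the last bin of a chromosome may be short;
bin indices are genome-global with chromosome offsets. Contact matrices are
dense, symmetric, float, with NaN marking missing pixels — at the desk
scales this package targets (up to a few thousand bins) dense storage is
simpler and faster than sparse.

## Balancing (iterative correction)

`balance_ice` iteratively rescales a raw count matrix so that every valid
bin has the same marginal. Defaults: `max_iters=500`, `mad_max=5`,
`ignore_diags=2`. Bins are masked when their log10 marginal deviates from
the per-chromosome median by more than `mad_max` median absolute deviations
(two-sided, in log space), or when their coverage is zero. The first
`ignore_diags` diagonals are excluded from marginal sums and blanked in the
output, since self- and adjacent-bin ligation artifacts dominate there.
Convergence is declared when the variance of the normalized valid marginals
falls below `tol` (default 1e-5; the underlying algorithm is agnostic to
this choice and the suite tests at 1e-12). The converged weights are
rescaled so valid marginals average exactly 1 — the overall scale of a
balanced matrix is arbitrary, and pinning it makes downstream values
deterministic. Non-convergence warns and returns the best iterate with
`meta["balance_converged"] = False`.

## Expected, O/E, and region groups

Distance-expected profiles are computed per *region group* (e.g. "chrX" vs
"autosomes" — the X and autosomes have distinct P(s), so pooling them would
bias O/E on both). Within a group, expected(d) is the mean of valid pixels
at separation d over all regions of the group; O/E divides each cis pixel by
its group's expected at that separation, making the per-distance mean O/E
exactly 1 within each group. Missing expected values propagate to NaN.

## P(s), log-derivative, and loop-size inference

P(s) pools valid pixels whose both ends lie in the requested regions,
binned geometrically in separation (default factor 2^(1/8)); the reported s
of each bin is the pixel-weighted mean separation, which removes most of
the bias of wide log bins. The log-derivative smooths log10 P with a
kernel-weighted *local-linear* fit in log10 s (σ = 0.1 by default) before
central differencing. Local-linear (rather than kernel-mean) smoothing is
exact on pure power laws, so a loop-free decay yields a flat slope with no
edge bias; plain Gaussian averaging biased the slope by up to 0.25 at the
profile edges. `infer_loop_size` reports the s of the most prominent local
maximum (scipy peak prominence) of the slope within a search range, with
ties broken toward smaller s, and returns None on monotone slopes — a pure
power law has no shoulder and no loop-size readout.

On simulated ensembles the log-derivative peak reads the scale of the
contact features, which sits somewhat above the realized mean loop length
when loops share loading sites (co-anchored loops interact at the sum of
their lengths); at the densities used in the benchmark scenarios the
readout is within ~10-30% of the simulator-logged mean.

## Compartments

EV1 is the leading eigenvector (dense symmetric eigensolver) of the Pearson
correlation matrix of the cis O/E submatrix over a region, with expected
computed within that region. Bins with too few finite pixels are dropped;
residual missing pixels are filled with the column mean before correlation.
The eigenvector is unit-norm and oriented so its correlation with a
user-supplied reference track (gene density, active-chromatin coverage, or
a known sign pattern in simulations) is non-negative.

Saddle strength ranks valid bins by EV1 and splits them into k equal-size
quantiles (default k=2, i.e. B and A halves). Strength pools per-pixel
means: mean O/E over within-quantile pixel pairs divided by mean O/E over
across-quantile pairs. Means rather than raw sums remove pair-count
imbalance; with equal-size halves the two coincide up to that imbalance.
The local profile tiles chromosomes into non-overlapping windows (default
2 Mb), recomputes EV1 and strength per tile, and reports one value per
tile; tiles with fewer than 10 valid bins are missing. `compare_conditions`
takes the elementwise ratio of two such profiles.

## Insulation

The insulation score at bin i is log2 of the mean balanced value in the
diamond [i−w, i) × [i, i+w), normalized by subtracting the chromosome mean
of log2 diamond means (equivalently, dividing by the geometric mean), so
scores average 0 per chromosome and are invariant to global rescaling.
Bins within w of a chromosome end are missing. The window is configurable
(500 kb default at 10-kb bins; the simulation benchmarks use 200 kb, on the
scale of the simulated loops) and recorded in the output metadata. Boundary
*calling* is deliberately not implemented — dips are interpreted relative
to flanks, and the quantitative object is the difference between conditions
(`differential_insulation`, after `remap_for_insertion` lifts the wild-type
map onto the insertion genome).

Insertion remapping carries inserted sequence as whole bins
(ceil(length/bin width)) so existing bin boundaries are preserved; inserted
bins carry no wild-type data and propagate NaN through differences.

## Pileups and signature scores

`on_diagonal_pileup` averages the (2f+1)×(2f+1) O/E submatrices centered on
anchor midpoints (anchor bin = bin containing the interval midpoint),
excluding missing pixels from the mean and dropping anchors within the
flank of a chromosome end. Strand is ignored: simulated and biological
barriers here are bidirectional.

The signature scores (`flame_score`, `anti_diagonal_score`,
`corner_peak_score`) quantify locus-directed features on simulated maps:
each compares the mean O/E of the feature's pixels against the distribution
of same-separation background pixels away from the locus, reporting the
feature mean and the background 95th percentile. Because ensemble-averaged
maps are smooth, the background 95th percentile is tight and weak secondary
signals can formally exceed it; the one- vs two-sided discrimination
therefore additionally requires dominance — a secondary anti-diagonal is
called only when its mean exceeds the flame arms it crosses. Under two-sided
point loading the anti-diagonal mean is ~3.4 (flame ~0.95); under one-sided
loading it is ~1.3 against a flame of ~1.5.

## ChIP tracks and expression

`rescale_xa` applies xf = (xi − A)/(X − A) with A the mean over autosomes
excluding chrII and X the chrX mean, yielding group means of exactly 0
and 1. chrII is excluded from the autosomal anchor because it is the
experimental chromosome in *rex*-insertion strains. `chrom_summary` applies
the same affine convention to per-chromosome means or peak counts (with a
`prescale` flag to summarize rescaled per-bin signal instead of raw).
Consensus peaks keep pooled peaks overlapping (≥1 bp) peaks in a *strict*
majority of replicate sets — with two replicates, both. `rex_signal_ratio`
uses a midpoint-centered fixed-width window (default 400 bp) and errors on
windows truncated by a chromosome end. Expression aggregation assigns genes
to bins by TSS with no length weighting; an optional permutation p-value
(label shuffles, default 10,000) tests domain-level repression, since no
specific parametric test is canonical here.

## The simulator

Fixed-timestep kinetics on a 1D lattice; all rates are per-step
probabilities. Per step and per LEF (in index order): unload with
probability `k_off` and reload instantly (constant LEF number, standing in
for exchange with a free pool at steady state); the tip advances one bin in
its extrusion direction with probability `v`, blocked by chromosome ends
and by any other LEF leg (no traversal — the standard mutual-blocking
assumption); the anchor takes an unbiased ±1 step with per-direction
probability `D`, confined behind its own tip and blocked by other legs.
Loading modes: `one_sided_rex_loading` (site sampled ∝ strength, anchor =
tip = site, random extrusion direction), `one_sided_uniform`,
`two_sided_uniform`, and `two_sided_point` (both legs extrude outward).

Barriers are bidirectional and *per-encounter*: the first time a tip
attempts to step onto a barrier bin it passes with probability 1 − p_stall,
otherwise it stalls there until the LEF unloads. This makes p_stall the
fraction of extruders the barrier blocks. A per-attempt retry rule was
rejected: with v = 1 a p_stall = 0.7 barrier would delay a tip by only ~3
steps against a ~25-step residence time, making 0.3 and 0.7 barriers
indistinguishable from no barrier in insulation — contrary to the graded,
probabilistic barrier behaviour the model is meant to capture (flames that
extend past a *rex* with reduced intensity).

Contact maps use an effective-distance bridge: within each sampled
configuration every anchor–tip pair is a unit-length shortcut in the
lattice path graph, and contact(i,j) is the ensemble mean of
(d_eff(i,j) + d0)^(−α), with α = 1 and d0 = 1 by default. d_eff is computed
exactly per configuration (Dijkstra from shortcut endpoints plus a min-plus
reduction; verified against dense all-pairs shortest paths). Without LEFs
this yields a pure power-law P(s) of exponent −α (the +d0 offset bends the
curve below ~20 bins); with LEFs it produces the target phenomenology:
P(s) shoulder, flames at loading sites, insulation at barriers, corner
peaks between paired sites, and weakened checkerboards when mixed into a
compartment pattern. This bridge is a deliberate minimal generative model,
not a polymer simulation: it has no excluded volume, no 3D embedding, and
its absolute contact values are in arbitrary balanced units.

Occupancy tracks count LEF legs (anchor + tip) per bin per sample, summing
to 2·n_lefs per chromosome — the in-silico ChIP analog. Synthetic
expression couples per-gene log2 fold change to occupancy at the TSS:
log2fc = −r·occupancy + N(0, noise_sd), with defaults (r = 0.5,
noise_sd = 1) chosen so individual genes are mostly not significant while
200-kb domain means separate cleanly — repression is detectable only at the
domain level.

## Frozen benchmark scenarios (`rexloop.scenarios`)

* `x_like`: 10 Mb / 1,000 bins at 10 kb, rex every 300 kb (strength 1,
  p_stall 0.7), 24 one-sided LEFs, k_off = 0.018 tuned so the realized mean
  loop is ~20 bins (200 kb), 250 samples every 8 steps after 500 burn-in.
* `barrier`: 4 Mb, uniform one-sided loading (20 LEFs, k_off = 0.03), one
  central rex with p_stall ∈ {0, 0.3, 0.7, 1.0}.
* `point_site`: 3 Mb, a single loading site, 3 LEFs, k_off = 0.02, run
  one-sided vs two-sided.
* `repression`: 5 Mb with rex sites confined to the central 1.5 Mb
  (20 LEFs), occupancy coupled to 600 uniformly placed genes.

These sizes keep every scenario within minutes on one CPU while leaving
clear stochastic margins; they are the package's own desk-scale choices.

## What the synthetic data does and does not show

The generator reproduces the qualitative and semi-quantitative structure of
dosage-compensation Hi-C/ChIP data (loop-size shoulder, barrier insulation,
flames, corner peaks, compartment dilution, X/A-style track conventions,
domain-level repression). It does not model read sampling noise, restriction
fragments, mappability, trans contacts, replication of biological variance,
or 3D polymer physics. Passing benchmarks therefore demonstrates that the
analysis stack measures what it claims on data with known ground truth —
not that the biological parameter values are correct. The no-LEF control is
an exact power law, so deviations of analysis output from −α there are pure
method error.

## Numerical details and degenerate inputs

* Balancing raises on all-invalid matrices; zero-coverage bins are NaN
  throughout downstream results.
* O/E at separations with zero or missing expected is NaN and propagates.
* `log2_ratio_map` defaults to pseudocount 0 with missing-on-nonpositive
  semantics; the pseudocount is configurable.
* `infer_loop_size` prominence ties break toward smaller s.
* EV1 on degenerate (rank-0 or constant) matrices raises; tiles that fail
  in the local profile are reported missing rather than erroring.
* Identical seeds give bit-identical ensembles; all sampling uses
  `numpy.random.default_rng`.
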