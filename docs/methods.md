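# Methods

## Problem setting

`fracnet` builds functional brain networks from region-of-interest
(ROI) BOLD time series and compares their global topology between two
groups. A subject is an N_roi x N_time matrix (one row per atlas
region, obtained either from delimited text or by voxel-averaging a
4-D NIfTI image within each label of a 3-D integer atlas). Each pair
of ROI series is scored by a dependence measure; the resulting
symmetric weight matrix is proportionally thresholded into binary
graphs whose clustering, path length, efficiency and small-worldness
are compared across groups with permutation statistics.

## Edge measures

**Linear correlation (lc).** Pearson's r. Because only the linear
correlation matrix contains negative entries, its absolute value is
taken before thresholding; mutual information and the fractal
dimension are nonnegative by construction.

**Mutual information (mi).** I(X, Y) in bits from an equal-width joint
histogram spanning each series' min-max range, with 0 log 0 = 0. The
default bin count per axis is ceil(sqrt(N)). Histogram MI on short
series carries a positive bias of roughly
(bins_x - 1)(bins_y - 1) / (2 N ln 2); with the defaults at N = 230
this is ~0.6 bits, which matters when comparing values across
conditions but cancels in rank-based thresholding.

**Box-counting fractal dimension (bcfd).** The pair of series is
rasterized into an M x M *pair image*: cell (i, j) counts the time
points whose amplitudes fall in the i-th bin of x and the j-th bin of
y; counts are affinely rescaled to integer gray levels 1..G (empty
cells at gray 1). Two counting variants are provided:

* `dbc` (default) — differential box counting of the gray-level
  surface. At scale s the plane is split into s x s blocks (partial
  edge blocks included, ceil(M/s) per side); boxes stacked over a
  block have height s' = ceil(s G / M), and a block spanning gray
  levels [g_min, g_max] costs ceil(g_max/s') - ceil(g_min/s') + 1
  boxes. A flat image therefore costs exactly one box per block and
  has dimension exactly 2.
* `binary` — counts blocks containing at least one occupied cell
  (point-set dimension in [0, 2]).

The dimension is the ordinary-least-squares slope of log N_r against
log(1/r) with r = s/M over scales s = 2, 4, ..., <= M/2 (any integer
scale set may be supplied). Box counts over the default doubling
ladder are computed by a min/max pyramid that is exactly equivalent to
the per-scale definition (blocks at scale 2s are unions of padded
blocks at scale s) and is verified against a nested-loop counter in
the tests.

Defaults: M = series length (the natural resolution of the
scatter plot), G = 64. Both are configurable. A caveat worth knowing:
with M equal to the series length the occupancy image is extremely
sparse (N points in N^2 cells), so the gray-level surface is spike-
dominated and the dbc dimension responds only weakly to the *strength*
of the dependence between the series at typical resting-state lengths
(~200-250 samples); denser binning (smaller M) makes the surface — and
hence the dimension — far more sensitive to correlation structure.

## Surrogate benchmarks

**Logistic-map complexity sweep.** Pairs of orbits of
x(n+1) = A x(n)(1 - x(n)) at a shared A in (3, 4), independent initial
conditions uniform on (0.01, 0.99), burn-in 100 steps, length 256,
50 replicates per level over A = 3.05, 3.15, ..., 3.95. Raising A
drives the map through the period-doubling cascade into chaos, so
pair similarity falls with A: median |r| is ~1 below the cascade
(both orbits phase-lock on the same low-period cycle) and ~0 in the
chaotic regime. Two estimator-driven facts about this construction
are worth stating plainly, because they are confirmed by the
benchmark itself: (i) a phase-locked period-2^k orbit pair has
histogram MI of exactly k bits (the joint distribution concentrates
on 2^k cells), while independent chaotic orbits retain only the
estimator bias (~0.6 bits), so MI *decreases*, on net, across the
cascade under this construction; (ii) chaotic pairs occupy many more
pair-image cells than near-degenerate periodic pairs, so the box
dimension *rises* with complexity. The benchmark reports whatever the
measures actually do; see the repository-level notes on which
directional claims this does and does not support.

**Randomization (similarity-decay) pairs.** (x, (1-a)x + a*eps) with x
white Gaussian and eps fresh noise matched to x's standard deviation.
The expected correlation is (1-a)/sqrt((1-a)^2 + a^2); the default
schedule takes 8 mixing fractions whose expected correlations fall
linearly from 1.0 to 0.3 (a conventional 30% terminal similarity).
The benchmark length is 1024: at that length the medians of all three
measures (|r|, MI, dbc dimension) decay monotonically from their
maximum on the identical pair, whereas at a few hundred samples the
sparse pair image makes the dbc median non-monotone near a = 0. The
closed-form correlation is additionally verified by Monte Carlo at
n = 10^4 within three standard errors.

## Network construction

Proportional thresholding keeps exactly
round(density * N(N-1)/2) strongest upper-triangle weights
(round-half-away-from-zero), with deterministic tie-breaking in
(row, column) order; the default density grid is 0.1 to 0.5 in steps
of 0.1. Thresholding is invariant under any strictly monotone
transform of the weights, and graphs across an ascending density grid
are nested. Self-connections are excluded throughout.

## Topology metrics and null models

* Clustering coefficient: mean over nodes of the realized fraction of
  neighbor pairs that are connected; degree < 2 nodes contribute 0.
* Characteristic path length: mean shortest-path length over
  *connected* node pairs, with the unreachable-pair fraction reported
  as an explicit flag (low densities routinely disconnect graphs).
* Global efficiency: mean 1/distance over all pairs, 1/inf = 0.
* Null model: degree-preserving double-edge swaps, 10 successful
  swaps per edge by default, ensembles of K = 100 by default (20 in
  the benchmark suites); graphs admitting no valid swap are returned
  unchanged with a warning.
* Small-worldness: sigma = (CC/C_rand) / (CPL/L_rand) over the
  ensemble means. Partially rewired ring lattices give sigma > 1;
  dense Erdos-Renyi graphs sit near 1.

## Group statistics

The test statistic is the difference of group means, with subject
labels shuffled preserving group sizes. Sampled tests use the add-one
p-value (1 + hits)/(n_perm + 1); an exact mode enumerates all label
assignments for small cohorts. Two-sided by default (direction is a
finding, not an assumption), 1000 permutations by default, one cell
per (measure, metric, density) with no correction across cells
(a Bonferroni option exists, off by default). Under group-identical
synthetic cohorts the empirical rejection rate at alpha = 0.05 is
~0.04 (500 simulations, 200 permutations).

## Synthetic cohorts

ROIs are partitioned into modules (default: 90 ROIs in 6 equal
modules); ROI i in module m of a subject with coupling c is
sqrt(c) * signal_m + sqrt(1-c) * noise_i with unit-variance white (or
AR(1), coefficient 0.3, off by default) latent signals, giving
expected within-module correlation exactly c and zero between
modules. Defaults mirror a typical two-group resting-state study:
17 vs 18 subjects, 230 time points; the benchmark comparisons use
15 vs 15 with couplings 0.6 vs 0.3.

What this generator does and does not emulate: it reproduces modular
correlation structure, sample-size noise and group-level coupling
differences, but has no hemodynamics, no spatial autocorrelation, no
hubs or long-range backbone, and no motion or physiological artifacts.
One structural consequence matters for interpreting the benchmarks:
under proportional thresholding both groups keep the same edge count,
and weakening homogeneous within-module coupling converts a few
within-module edges into random cross-module edges. Random cross
edges are shortcuts, so the weak-coupling group's graphs show *lower
clustering* but *higher* global efficiency and *shorter* paths. A
deficit in efficiency alongside a deficit in clustering — the pattern
reported for patient populations — requires structure this block
model deliberately omits (e.g. weakened long-range hub connectivity),
so passing or failing the directional efficiency check on this
generator says nothing about real patient data.

## Numerical choices

* All validation is strict: constant series, degenerate densities,
  asymmetric matrices and unknown labels raise errors naming the
  offending input rather than propagating NaNs.
* Correlations are clipped to [-1, 1] against rounding; weight
  matrices are symmetrized exactly after the corrcoef fast path.
* Every stochastic routine takes an explicit seed (numpy Generator
  seeding; child seeds drawn below 2^31); there is no global state.
* Matrices are serialized at full precision (%.17g) so write/read
  round-trips are bit-exact, and every CLI stage writes its resolved
  configuration for bit-exact replay.

## Known limitations

* Histogram MI is biased upward at short lengths; no bias correction
  is applied (rank-based thresholding is unaffected).
* The dbc dimension at M = series length is insensitive to dependence
  strength for short series (see above); users wanting a sensitive
  edge weight should lower M or use the binary variant.
* CPL on disconnected graphs is a connected-pairs mean; alternative
  conventions (largest component, harmonic substitution) are not
  implemented.
* No multiple-comparison correction across densities/metrics by
  default, mirroring common per-threshold reporting practice.
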