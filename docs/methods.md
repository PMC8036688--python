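# Methods

This note records the models implemented by `luces`, the defaults and
conventions chosen where the method family leaves them open, and what
the synthetic test-bed does and does not establish about real data.

## Land-use representation

Categorical rasters carry six classes (1 cultivated, 2 woodland,
3 grassland, 4 water, 5 built, 6 unused) plus nodata (0); the default
cell is 30 m × 30 m, carried as metadata and used for all area
conversions (1 cell = 0.09 hm²).  Rasters round-trip through ESRI ASCII
grids, a plain-text format whose header stores cell size and nodata, so
artifacts remain diffable and portable.

## Markov demand stage

The transition matrix is the row-normalised cross-tabulation of classes
over jointly active cells of two snapshots; empty source rows become
identity rows (an absent class is assumed to persist).  Demand at the
horizon is `counts_t1 · Pˢ` with the number of steps exposed (one step
reproduces a snapshot-interval projection; annualised chains are the
caller's choice).  Projections are rounded by largest remainder so the
total cell count is conserved exactly — the CA allocator needs integer
targets — and rounding moves no class by a full cell.

Scenario adjustment is an explicit, configurable convention: protection
scenarios floor the protected classes (cultivated; or woodland + water)
at their current counts and subtract the total deficit from built-land
demand, conserving the total.  This is the simplest rule that produces
the qualitative behaviour protection policies are meant to have —
built-land growth damped, protected stock non-decreasing — and it is
deliberately kept separate from the estimator so other rules can be
swapped in via per-class floor overrides.

## Suitability stage

A single-hidden-layer perceptron (logistic hidden units, softmax
output, cross-entropy loss; scikit-learn's `MLPClassifier` underneath)
maps min–max-normalised driver vectors to class probabilities.
Defaults: 12 hidden units, 200 epochs, learning rate 0.01, training
sample 20 · classes · drivers cells drawn class-balanced without
replacement.  These sizes are unremarkable for single-layer suitability
networks and are all exposed in config.  Network outputs are
renormalised per cell so the six probabilities sum to exactly 1 — the
output layer is treated as producing scores, normalisation is imposed
as a constraint rather than assumed from the architecture.  Classes
absent from the training sample receive probability zero.  Model
quality is reported as one-vs-rest ROC AUC per class; classes absent
from the reference map are reported as missing rather than silently
averaged.

## Cellular-automata allocation

Per iteration and cell, the total conversion score multiplies four
factors: suitability sp(p, k); the Moore-neighborhood effect Ω — the
count of class-k cells among the 8 neighbours divided by 8, weighted by
ω_k (default 1 for every class), with out-of-bounds and nodata
neighbours counting zero; the per-class adaptive inertia; and the cost
factor (1 − sc[c→k]) with a zero diagonal (staying is free) and sc = 1
forbidding a conversion.  Protection scenarios forbid conversion out of
the protected classes; the natural scenario uses a uniform 0.5
off-diagonal cost.

Adaptive inertia: with demand gap D = demand − count, a class's
coefficient is unchanged while |D^{t−1}| ≤ |D^{t−2}|, is multiplied by
D^{t−2}/D^{t−1} when a worsening overshoot (both gaps negative) and by
D^{t−1}/D^{t−2} when a worsening undershoot (both positive), clamped to
[10⁻³, 10³]; a zero previous gap leaves it unchanged.  This is the
canonical FLUS-style rule; the three case conditions are stated here
explicitly because variants circulate with ambiguous boundaries.

Allocation bookkeeping: cells are visited in a freshly randomised order
each iteration (removing raster-order artifacts); only cells whose
current class is *over* demand may change, and the roulette draws among
the classes currently *under* demand with probability proportional to
their scores — if every candidate scores zero the cell keeps its class.
This demand gating makes the absolute gap of every class non-increasing
(a tested invariant) and convergence typically takes a handful of
iterations.  Inside the allocator the neighborhood factor is floored at
10⁻⁴ so a class with no local presence can still be seeded where demand
requires it; the `neighborhood_effect` operation itself is exact and is
verified against a brute-force 8-neighbour count.  Frozen cells
(constraint mask 0) and nodata never change.  Convergence tolerance
defaults to 0.1% of active cells; infeasible demand (below a class's
frozen stock, or beyond the convertible pool) raises an error naming
the class.

## Validation metrics

Overall accuracy, Cohen's kappa ((p_o − p_e)/(1 − p_e); defined as 1
when both maps are constant and equal), and the four-component Pontius
figure of merit B/(A+B+C+D), where A = missed change, B = change
predicted with the correct class, C = change predicted with a wrong
class, D = false alarms.  FoM is 0 with a warning when neither map
changes anywhere.

## Equivalent-factor valuation

The packaged coefficient table (11 services × 6 classes, units
100 yuan·hm⁻²·yr⁻¹) is a regional table for a central-China prefecture;
negative built-land entries (water supply, gas regulation, environment
purification) are net disservices and are retained in all sums.  An
alternative table can be supplied as CSV, or built by rescaling
dimensionless base equivalents with a regional unit value E.

E is computed literally as (1/7)·Σ m_i p_i q_i / M with m sown area
(hm²), p price (yuan/t), q yield (t/hm²).  The packaged crop statistics
interpret the source yearbook's per-crop yield column as t/hm² (the
printed figures, 1.4–6.6, are plausible per-hectare yields but
implausible regional totals); with that reading E ≈ 1729 yuan/hm².
Reported regional values of E derived from the same statistics differ
by an order of magnitude depending on how that units ambiguity is
resolved; the package implements the formula literally and leaves the
table's calibration to the user rather than reverse-engineering any
particular printed value.  No downstream computation in this package
depends on E — the coefficient table is shipped already calibrated.

Grid aggregation assigns cells to the square analysis grid containing
their centre (default 1 km); UESV divides each grid's ESV by its
*actual* member area so smaller edge grids are comparable to interior
ones, and the sum of UESV · area over grids reproduces the whole-map
total to within rounding (a tested invariant).  UESV levels 1–5 come
from Fisher–Jenks optimal breaks implemented by dynamic programming
over prefix sums and verified against exhaustive partition search;
with fewer distinct values than classes the degenerate classes collapse
with a warning.

## Spatial association

Weights are queen contiguity on the analysis grid (rook available),
row-standardised, restricted to grids containing active cells; isolated
grids are flagged as islands and keep zero rows.  Variables are
standardised with the population (1/n) standard deviation, which makes
the mean of the local statistics equal the global Moran's I exactly
(asserted to 10⁻¹⁰).  The global statistic is not clipped to [−1, 1];
extreme weight configurations can exceed that interval slightly.

Significance uses conditional permutation: the focal cell's value is
held fixed while neighbour values are drawn without replacement from
all other locations, with one shared set of truncated permutations
across cells (999 replicates by default); the pseudo p-value is
two-sided on |I|.  Cells with p < α (default 0.05) are labelled
HH/LL/HL/LH from the signs of the focal z-score and the spatial lag;
HH + LL grids are counted as synergy, HL + LH as trade-off.  The test's
type-I error is calibrated on spatially independent fields (0.05 ±
0.02, a tested property).

## Synthetic test-bed

Drivers are white noise smoothed with a Gaussian kernel of width
`corr_length` (spatial autocorrelation is what downstream stages need;
no geostatistical fidelity is claimed), a DEM-like field with
finite-difference slope and aspect, two smooth socioeconomic fields,
and four Euclidean-distance-to-random-point accessibility layers.  The
initial map draws each cell from a multinomial logit on the normalised
drivers; the default weight matrix uses N(0, 6²) entries with zero row
sums, which balances expected class shares while keeping a strong,
recoverable class–driver signal; optional 3×3 majority smoothing adds
contagion.  The second date evolves each cell independently through a
known row-stochastic matrix whose defaults encode strong persistence
with a drift toward built land.  Constraint masks freeze contiguous
random patches of the protected classes grown by seeded breadth-first
search.

What passing tests show: the estimators and allocators recover planted
parameters at the stated statistical tolerances, conserve what they
must conserve, and agree with brute-force oracles.  What they do not
show: performance on real interpreted imagery, where drivers are
cross-correlated with class history, transitions are spatially
heterogeneous, and class boundaries follow cadastral and terrain
structure none of which the generator emulates.

## Reproducibility

All generators and stochastic stages take explicit seeds; pipeline runs
derive named substream seeds (truth/drivers/evolve/mask/ann/ca/perm)
from one master seed via `SeedSequence`, and every artifact bundle
carries a manifest of SHA-256 hashes that reruns reproduce exactly.
Default problem sizes (64×64 landscapes, 199–999 permutations, 256×256
recovery grids) keep a full scenario run in the low seconds on a single
core while leaving the statistical tests adequately powered.
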