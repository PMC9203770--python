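# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `ltpsim`, in the order the pipeline runs.

## Landscapes

A `LandscapeGrid` is a rectangular raster of cell types {land, ocean, lake,
river} with elevation (m) on land, 0-based (row, col) indexing, row 0 at the
northern edge, coordinates at cell centres.  East–west spacing may vary per
row (cos-latitude correction) when the raster is geographic; synthetic grids
use constant spacing.  Periodic (toroidal) topology is supported for
all-land flatland only.

The synthetic generator is fixture plumbing that emulates the qualitative
features of real terrain, not any specific region.  Coastlines are carved by
thresholding smooth spectral noise at the quantile matching the requested
land fraction (water components touching the border become ocean, enclosed
ones lakes); elevation is power-law (1/|k|^β) spectral noise, shifted
non-negative and scaled to a requested amplitude; rivers are 8-connected
Bresenham rasterisations of polylines.  Everything is a pure function of the
spec (seed included): identical specs give bit-identical grids.  What the
generator does **not** emulate: drainage-consistent river networks, valley/
ridge correlation between rivers and relief, coastline fractality at scales
below the noise cutoff, and land-cover variation.  Tests passing on these
landscapes therefore demonstrate the mechanics and the qualitative
phenomenology (barriers, detours, heterogeneity-driven symmetry breaking),
not calibrated realism for any actual geography.

Raster I/O uses the ESRI ASCII grid text format (elevation + integer
cell-type codes + JSON sidecar).  Real-raster ingestion applies block-median
resampling to elevation (robust to outliers) and block-majority to cell
types, and can drop rivers of hydrologic class ≤ 1 from a companion
river-class raster.

## Movement costs and effective distances

A step to one of the eight adjacent cells costs

    horizontal_km × type_multiplier × exp(k·|slope|)  + embark surcharge,

with slope = rise/run (dimensionless), and the surcharge applied on every
land↔water transition.  Diagonal steps use the true centre-to-centre
horizontal distance.  Pair multipliers are the mean of the two cells'
per-type factors (impassable wins), which makes the cost model symmetric,
hence r_ij = r_ji.

Scenario defaults (config values, chosen once for qualitative plausibility;
they are the package's own stand-ins, not externally derived coefficients):

| scenario     | slope k | water multiplier | surcharge |
|--------------|---------|------------------|-----------|
| flatland     | 0       | impassable       | —         |
| coastline    | 0       | impassable       | —         |
| elevation    | 3.5     | impassable       | —         |
| water_bodies | 3.5     | 0.5× land        | 2 km      |
| (Roman epoch)| 3.5     | 0.25× land       | 2 km      |

k = 3.5 is a Tobler-inspired symmetric slope penalty (≈ ×1.4 per 10% grade);
water at half land cost with a 2 km embarkation surcharge makes coastal
shipping attractive for medium hauls but not for single-cell hops; the Roman
epoch halves the water cost again (sailing comparably more efficient than
pre-modern land transport).  A side effect of making rivers navigable in
`water_bodies` is that they also stop blocking perpendicular crossing — a
crossing is land→river→land at two surcharges — which is the intended
reading of treating the river uniformly as a transport medium.

Locations are sampled one per spacing×spacing block at the land cell nearest
the block centre (lexicographic tie-break); blocks without land get no node.
Effective distances are Dijkstra on the sparse cell graph
(`scipy.sparse.csgraph`), keeping node pairs within a cutoff `r_max`.
Stored least-cost paths are recovered by backtracking on the source's
distance field, breaking equal-cost ties lexicographically by the
predecessor's (row, col) — deterministic paths at no extra cost.
Disconnected location sets are reported (component list), never silently
truncated.

**Edge cutoff.** The deterrence factor must satisfy ε·f(r) < 2 on every
retained edge, else the linear connectivity map oscillates divergently
(|1 − εf| > 1).  With the default ε = 0.1 this caps r/R at ≈ 2.2, so the
default cutoff is `r_max = 2R` (equilibrium connectivity at 2R is already
suppressed ≈ 5.4× relative to r = R).  A wider cutoff such as 5R is
admissible only with proportionally smaller ε; the runner leaves both as
config values and `update_connectivity`/`critical_d` check the bound.

## The coupled dynamics

Within one step, the connectivity map is applied first (using x(t)), then
the popularity map (using w(t+1)).  The maps' fixed points are order-
independent; the sequential order only affects transients, and the
stability analysis linearises exactly this composition.  Because T is
column-stochastic, the popularity map is algebraically
`x(t+1) = d·T x(t) + (1−d)·u` with u the dispersion target (uniform 1/N, or
C_i/ΣC when the optional capacity hook is supplied), which conserves
Σx = 1 exactly on the constraint manifold; off the manifold, Σx − 1
contracts by d per step.  Nodes with zero incident connectivity fall back
to self-retention (their column of T is the identity), with a warning.

Defaults: ε = 0.1, d = 0.9, initial fluctuation σ = 0.01 (x ∝ 1 + σu,
u ~ U(−1,1), seeded), convergence when max_i |Δx_i|·N < 10⁻⁸, step budget
20 000.  Non-convergence returns the final state with a warning flag rather
than raising; saturated patterns can keep creeping (slow coarsening) at
residuals just above tight tolerances.

**Counterfactual (geographical determinism).**  Connectivity is frozen at
the uniform-population equilibrium w_ij = (1/N²)/f(r_ij) — distance decay
only — and the popularity map alone is iterated to stationarity.  This is
the most literal reading of "same landscape, no reinforcement"; it is a
reconstruction (the choice is ours) and is documented as such.

**Net traffic.**  Per-edge flux φ_ij = T_ij x_j + T_ji x_i (total per-step
probability flow in both directions) deposited on every cell of the edge's
stored least-cost path.  This definition is likewise the package's own
reconstruction of a traffic field from the model state.

**Ramped epochs.**  A ramp schedule holds cost surface and R constant
within an epoch and recomputes effective distances only at epoch
boundaries.  Connectivity is carried across a boundary on edges common to
the old and new graphs; newly appearing edges start at the connectivity
equilibrium for the current x; vanished edges are dropped.  The default
historical preset steps R through 8 → 40 km with per-epoch
quasi-equilibration and snapshots at R ∈ {8, 22, 24, 40} km.  A continuous
ramp is a config away (many short epochs); the stepwise form is the default
because distance recomputation is the expensive operation.

## Historical initial conditions

City tables (name, lon, lat, population) are snapped to the nearest
location node by least-cost distance under the epoch's cost surface
(Euclidean fallback when unreachable).  The rural total is spread over
locations proportionally to the distance-discounted score
s(i) = Σ_u (r_{i,j_u}/R)⁻¹ · Pop(u) with R = 8 km (walking scale); a city's
own node is excluded from its sum (its population sits there directly) and
unreachable cities contribute nothing.  Output totals are exact:
Σcity + rural.

## Stability analysis

On periodic flatland with one location per cell, every node is equivalent
and the coupled maps have a homogeneous fixed point (x = 1/N, w at the
connectivity equilibrium).  The analysis builds the exact Jacobian of the
sequential one-step map in the joint (x, w) coordinates and
block-diagonalises it by translation symmetry: for each Fourier mode k the
block couples the popularity amplitude X with one connectivity amplitude
W_b per bond-offset class (10 classes for the 5 km cutoff on 2 km spacing).
The full-lattice Jacobian is also constructed densely and its spectrum
verified against the union of block spectra and against central-difference
differentiation of the simulator map (to 10⁻⁶ on a 6×6 lattice).
Perturbation bookkeeping respects the Σx = 1 geometry: the k = 0 popularity
eigenvalue is d (contraction back onto the manifold), and instability is
declared only for nonzero-wavenumber modes.

`critical_d` scans d over [0, 1] (101 points by default), brackets the
first d at which some nonzero-k growth factor modulus exceeds 1, and
bisects to 10⁻³.  Setting the block eigenvalue to 1 analytically shows the
threshold does not depend on ε (a steady bifurcation determined by the
fixed-point structure), which the tests confirm numerically.

**Baseline calibration.**  The frozen `FLATLAND_BASELINE` preset is a
16×16 periodic lattice, 2 km spacing, 5 km cutoff, ε = 0.1, R = 2.5 km.
The threshold on this family of lattices turns out to be structurally
d_c ≈ 0.800: over the whole admissible R range (2.3–8 km under the εf < 2
bound) it varies by less than 0.01, and it is identical on 8×8 and 16×16
lattices once the unstable wavelength (~12 km) fits the domain.  R = 2.5 km
was fixed once and frozen; nothing else was tuned.

**Pattern classification.**  For simulated fields, the dominant wavenumber
is the argmax of the 2-D Fourier amplitude over nonzero modes, reported as
zero (pattern-free) when that peak is below 10⁻³ of the k = 0 amplitude
(total mass).  A converged uniform state sits ~10⁻⁸ relative; a saturated
pattern sits ~10⁻¹ — the classification is insensitive to the threshold
over five orders of magnitude.

## Evaluation

KL distance uses natural logarithms (nats) on internally normalised
vectors, in the direction D_KL(reference ‖ simulation).  Where the
simulation assigns zero to a populated region the result is +∞, surfaced
as such; an explicit epsilon-floor flag exists for exploratory use and is
off by default.  Note the base only rescales absolute KL values; orderings
and relative improvements are base-independent.  Pearson/cosine use the
standard definitions on raw per-region vectors; Pearson is reported as
undefined for zero-variance input.  Polygon aggregation assigns a cell to
the region containing its centre, ties to the lowest region id; aggregation
errors list the offending unlabelled populated cells.  Ensemble statistics
use the n−1 (sample) standard deviation.  Rank-size tables re-aggregate a
population field onto coarse blocks (default 6 km in the runner's
vocabulary) and report densities, ranks and the empirical CCDF; no power-law
exponent is fitted.

## Reproducibility

All randomness flows through `numpy.random.default_rng` seeded from the run
config; one master seed expands into per-stage children via
`SeedSequence.spawn`.  Run directories carry a manifest (canonical config
JSON + SHA-256, seeds, package/library versions); re-running from a
manifest reproduces node/edge/traffic outputs byte-for-byte.  Config
schemas reject unknown keys, so a typo in a cost parameter fails loudly
instead of silently using a default.

## Problem sizes and limitations

The test and acceptance workloads use desk-scale grids: 16×16 for the
dispersion analysis, 40×40 periodic flatland for the pattern bifurcation,
a 36×30 synthetic coast/relief landscape (~190 locations) for the
counterfactual comparison, and ≤ 20×20 grids for oracle-exact shortest-path
checks — sizes at which every quantity can be recomputed exactly or against
brute force.  The same code paths scale to country-scale rasters, but
memory in the distance stage grows with (locations × cells) and no
out-of-core support is provided.  Other known limitations: no congestion,
engineered infrastructure, hydrological river derivation or landscape
change over time; no stochastic migration shocks (the dynamics are
deterministic); boundary effects at the simulation region's edge are not
corrected; and the spatially varying capacity C_i is exposed as a hook but
not exercised by any preset.
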