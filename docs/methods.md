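# Methods

## The analysis in one paragraph

`habsel` quantifies habitat selection from use/availability data of the
kind produced by territory-mapping surveys of farmland birds (the built-in
vocabularies and defaults mirror grey partridge *Perdix perdix* surveys:
square study units of 618 m side, winter coveys of more than two birds,
spring territories indexed by calling males).  *Use* is the habitat
composition of a circular plot (default 100 m radius, ≈3.14 ha — a
breeding-season home range) around each bird location; *availability* is
the composition of the bird's landscape, either averaged over all survey
squares or taken per square.  Selection per habitat type i is Manly's
alpha,

    α_i = (r_i / n_i) / Σ_j (r_j / n_j),

rescaled to Chesson's electivity

    ε_i = (m·α_i − 1) / ((m − 2)·α_i + 1) ∈ [−1, 1],

with m the number of available habitat types.  ε = 0 means use proportional
to availability; the transform makes values comparable between units that
face different m, which matters in per-square mode.  Per habitat, the mean
of unit-level ε values over units is given a bias-corrected and accelerated
(BCa) bootstrap confidence interval (1500 resamples, 95%); a CI whose
endpoints share a sign classifies the habitat as preferred (+) or avoided
(−), an interval straddling zero (or touching it exactly) is not
significant, and habitats backed by fewer than 7 units are not tested at
all.

## Geometry

Patch maps come in two representations with one contract: a regular grid
of habitat codes (cell-centre membership decides whether a cell is inside
a plot; default cell 1 m for rasterised inputs, 6 m for synthetic maps)
and non-overlapping labelled polygons (exact intersection areas through
shapely).  The two agree on plot composition to well under 0.01 at 1 m
cells and converge as the cell size shrinks; a test asserts this at three
resolutions.  Plots are clipped at the square boundary and renormalised
over the clipped area, because availability was mapped per square and an
edge plot sampling a neighbouring square would compare use against habitat
the unit was never offered.  Unlabelled area above a 1% tolerance is an
error naming the square, not a silent renormalisation.

Distance to infrastructure is the Euclidean distance to the nearest
patch boundary of an infrastructure code (roads, field paths, settlements,
parks, power poles, windmills, construction sites at the rough scale;
field paths, gravel walks and tarred roads at the fine scale), zero inside
such a patch and undefined — never zero — when a map holds none.

"Super hedges" (hedges still useful to partridges rather than overgrown
treelines) are classified by strict thresholds: height > 4 m, width > 2 m,
understory cover > 0.70, all three required, configurable.  The height
criterion looks contradictory for a bird that favours low, bushy hedges;
the thresholds are implemented verbatim as configured defaults rather than
reinterpreted.

## Availability frames

Two axes are configurable and matter scientifically:

* **mode** — `averaged` (one frame for everyone, the rough-scale
  convention) vs `per_square` (each unit scored against its own square;
  avoids crediting units with habitat types their square never offered,
  at the cost of m varying between units).
* **source** — `square_map` (whole-square composition; the default) vs
  `reference_plot` (the circular plot at the square centre, emulating the
  field protocol).  Centre plots sample ~8% of a square, so a habitat type
  a bird used can be absent from every centre plot; `manly_alpha` treats
  positive use with zero availability as an error (it signals a frame
  mismatch) instead of silently dropping the type, which is why the robust
  whole-map source is the default.

Types with zero use *and* zero availability are dropped before m is
counted.  A square offering a single habitat type cannot support
electivity (m ≥ 2) and is skipped with a warning in per-square mode.

## BCa bootstrap

The interval for a habitat's mean ε resamples the unit-level values with
replacement (B = 1500 by default).  The bias correction is
z₀ = Φ⁻¹(p) with p the fraction of resampled means below the observed
mean; resampled means exactly equal to it count one half, which keeps z₀
finite on discrete ε sets, and p is clipped to [1/(B+1), B/(B+1)] so a
one-sided resampling distribution cannot push Φ⁻¹ to ±∞.  The
acceleration is the jackknife third-moment estimate
a = Σd³ / (6 (Σd²)^{3/2}) with d the deviations of leave-one-out means;
a = 0 when all leave-one-out means coincide.  Adjusted percentiles are
read from the bootstrap distribution with linear interpolation between
order statistics.  An all-equal sample yields the point interval [v, v].
Each habitat draws from an independent substream derived from the master
seed and a CRC-32 of the habitat code, so results are reproducible and
independent of habitat ordering; the seed is recorded in the run metadata.

Calibration (recomputed by `tests/test_acceptance.py` and
`scripts/acceptance.py`): empirical coverage for a Gaussian mean at n = 30,
B = 1500 over 500 replicates is ≈0.93–0.95; on symmetric samples the BCa
endpoints agree with plain percentile endpoints to < 0.02 (n = 200,
B = 5000); scipy's independent BCa implementation reproduces the endpoints
on identical inputs.

No multiple-testing correction is applied across habitats, and no
studentised or double bootstrap is offered — the one-sample BCa on the
mean is the method, applied per habitat.

## Landscape metrics

A *patch* is a maximal connected region of one habitat code: 4-neighbour
connectivity by default on grids (conservative fragmentation counts; 8 is
available), merged touching same-code features on polygon maps.  Change
tables report, per year and scope (all squares / squares with bird
presence / plots per bird / plots per territory), the average patch count
and mean patch area, the same for the infrastructure subset, and total
infrastructure area.  "Average area size" averages each square's mean
patch area over squares by default; a pooled-patches alternative is a
flag, since either reading is defensible.  Years with no units in a scope
are flagged empty rather than reported as zero.  Diversity is the
Shannon–Wiener index H = −Σ p ln p in nats (natural log, the convention of
the vegan ecosystem; the base is configurable).  Seasonal
nearest-infrastructure summaries report medians with a 1000-resample
percentile-bootstrap standard error, since a plain SE formula for a median
would need a density estimate.

Mixed-model inference on these responses (used-vs-available H, counts vs
year, distances vs season, square as random factor) is deliberately not
reimplemented; `diversity_table` and the change tables are tidy per-unit
exports meant for an external mixed-model fit.

## Synthetic data and what passing tests mean

The generator emulates the *statistical structure* of a peri-urban
farmland survey: 20 squares of 618 m, a closed vocabulary, rising patch
counts and infrastructure over survey years, winter coveys (sizes uniform
on 3–15) and single-record spring territories.  Landscapes are built by
nearest-nucleus partition of each square (nuclei on a jittered lattice,
their count setting the fragmentation trend) with the type multiset
allocated per square by stratified largest remainder and assigned to
regions by a greedy anti-adjacency colouring — without it, neighbouring
same-type regions merge and the realized patch count drifts below the
configured trend.  Infrastructure is overlaid as small non-overlapping
blocks with configured per-year count and area, reflecting that
infrastructure patches are far smaller than field patches.  One master
seed governs landscape, placement and bootstrap substreams.

Birds are placed by a weighted selection model: a location lands in a grid
cell with probability proportional to the selection weight w of the cell's
type, uniform within the cell.  Under this model the expected alpha is
w_i / Σ_j w_j independent of the availability shares, so every scenario
has a closed-form true ε — the target of the recovery tests.

Unit-level ε is a nonlinear function of the unit's estimated use profile,
so its mean across units is a biased estimate of the true ε when units
carry few locations: a delta-method expansion gives a bias of order
−1.2/L for the neutral type at m = 6 with L locations per unit, and a plot
radius comparable to the patch grain additionally shrinks use towards
availability.  The calibration scenarios therefore use many locations per
unit and a plot radius small against the patch grain (recovery: 40 units ×
40 locations, 20 m radius on 6 m cells; neutral type-I: 20 units × 100
locations), while the field-shaped demo scenario keeps the realistic one
record per unit and 100 m plots.  Consequence for real data: with one
location per bird, per-habitat mean ε is pulled towards the extremes
relative to population-level selection, and the BCa interval quantifies
only sampling noise, not this estimator bias.

The generator does not model bird movement, detection probability (the
field protocols' transect and playback counts are emulated only as unit
counts), linear road geometry, spatial autocorrelation between years, or
digitisation error in maps.  Passing recovery tests therefore demonstrate
the correctness of the computational chain, not robustness to those field
realities.

## Numerical choices and degenerate inputs

* Composition proportions must sum to 1 within 1e-9; alpha normalisation
  is asserted at the same tolerance.
* m < 2 anywhere is an error, as is an all-zero use profile.
* ε round-trips through its inverse α = (1+ε)/(m−(m−2)ε) to 1e-12 (the
  inverse exists for testing, not as an alternative index).
* Pearson trend correlation requires ≥3 year/total pairs and nonzero
  variance on both axes.
* Grid/polygon representation differences are bounded by the rasterisation
  test; patch areas on grids sum to the map area within one cell.
* All writers are deterministic; a config hash plus the seed fully
  determine every numeric output of `run_analysis`.

## Problem sizes used in the self-checks

Recovery: 50 replicates of 20 squares × 103×103 cells, 40 units × 40
locations, B = 1500 (~10 s).  Neutral type-I: 100 replicates of 20 units ×
100 locations (~20 s).  Coverage: 500 Gaussian samples of n = 30 at
B = 1500 (~10 s).  These sizes give Monte-Carlo standard errors of about
1 percentage point on the reported rates while keeping the whole suite
fast enough to run on every change.
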