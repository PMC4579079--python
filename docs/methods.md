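# Methods

## The model

`deforisk` is an annual, gridded scenario generator for forest-cover
change.  It separates *how much* forest a region loses — a prescribed
macro-regional net rate — from *where* the loss lands, which is decided
by a per-cell multiplicative risk field built from static local
drivers.  The intended use is translating coarse regional land-use
scenarios onto the fine grid of a vegetation or land-surface model; in
this package the model runs offline, feeding each year's modified cover
map into the next annual step.

### Risk factors

For each cell *i* the total risk is the product of six factors,

    r_tot = r_road · r_river · r_pop · r_park · r_log · r_frag.

Each driver uses the simplest two-constant form: a maximum relative
impact *k* (dimensionless; only the ratio across cells matters, since a
region-wide scale factor absorbs any common multiple) and a spatial
scale *l* (km):

- **Roads / rivers** — `r = (k − 1)·exp(−d/l) + 1`, with *d* the planar
  Euclidean distance (km) to the nearest rasterized feature cell.
  Defaults: k = 3.5 for both; l_road = 100 km, l_river = 1 km.
- **Population** — a distance-weighted population density
  `p̄_i = Σ_j p_j e^(−d_ij/l_p) / Σ_j e^(−d_ij/l_p)` (l_p = 15 km) is
  mapped through the saturating law
  `r = (k − 1)(1 − exp(−p̄/d_p)) + 1` with d_p = 100 people km⁻²: empty
  country is neutral, dense hinterland saturates at k = 3.5.  The
  weighting makes a small nearby town and a large distant city carry
  comparable risk.
- **Protected areas / logging concessions** — constant factors k_park
  (default 1.0, i.e. no enforced protection) inside parks and k_log
  (default 1.3) inside concessions, 1 elsewhere.
- **Fragmentation** — a beta-shaped function of cover.  With the local
  cover *f* and its kernel-weighted neighbourhood mean *f̄*
  (l_f = 2.5 km),

      r_frag = (k_frag − 1) · f^p · (1 − f̄)^q / 0.5^(p+q+1)      (default)

  with k_frag = 3.5, p = q = 4.  It vanishes on bare ground and in
  unbroken forest and, for homogeneous cover, peaks at 50% — the edge
  effect by which fragmented forest is cleared fastest.

### Fragmentation normalization and identifiability

The default ("as_printed") form evaluates to 2·(k_frag − 1) at
homogeneous half cover, not to k_frag.  A second variant
("k_at_half"), selectable via `RiskParams(frag_normalization=...)`,
uses `(k_frag − 1)·f^p(1 − f̄)^q / 0.5^(p+q) + 1`, which equals exactly
k_frag at half cover at the cost of a neutral floor of 1 instead of an
annihilating 0.

The default form has a consequence worth knowing: it is
`(k_frag − 1)` times a k-independent shape, so changing k_frag
multiplies the *whole* total-risk field by a constant — which the
regional scale factor α cancels exactly.  Deterministic simulations
are therefore invariant to k_frag under the default form (until
clamping introduces nonlinearity); a factorial sweep over k_frag
produces exact ties.  The parameter-recovery experiment in the
acceptance suite uses the "k_at_half" variant, under which k_frag
shifts the balance between fragmentation and the other drivers and is
identifiable.

### Allocation

Each macro-region Ω carries a prescribed net rate M(t), a signed
fraction of the region's current total cover per year (negative = net
loss; the Congo demonstration value is −0.0001 yr⁻¹, i.e. 0.01% a
year).  Reforestation regrows toward a population-discounted potential
cover,

    A_i = max(0, (f_t·exp(−p̄_i/τ_rp) − f_i) / τ_r),

with f_t = 0.86 (potential cover of the dense-forest domain),
τ_r = 60 yr and τ_rp = 200 people km⁻² — near dense population,
conversion is assumed permanent and the recoverable potential shrinks.
The scale factor

    α_Ω = (M·Σf − ΣA) / Σ(r_tot·f)

makes the risk-proportional gross change D_i = α·r_tot,i·f_i close the
budget ΣD + ΣA = M·Σf exactly (an algebraic identity, asserted to
1e-12 in the tests).  New cover is clamped to [0, f_t]; demand unmet
because of clamping is redistributed by re-solving α over the
unclamped cells, up to 20 iterations or a relative residual of 1e-6,
after which a warning is logged.  Reforestation is computed once at
the start of the step and held fixed during rebalancing.  Forest loss
and regrowth are mirrored in a two-category PFT bookkeeping (forest ↔
replacement), conserving per-cell sums.

Risk is recomputed every year from the evolving cover; only the
fragmentation factor actually changes, since the driver maps are
static.  This "static risk maps" assumption is the model's main
limitation for long projections — no new roads or towns appear as
population grows.

## Numerical choices

- **Distances** are planar Euclidean in km, computed from the grid's
  nominal resolution (5 km by default).  The intended domains span a
  few degrees around the equator, where plate-carree distortion is
  well under the parameter uncertainty.  Distance-to-feature fields
  use an exact Euclidean distance transform between cell centres.
- **Kernel means** (forest density, weighted population) are computed
  by FFT convolution with the exponential kernel truncated at 30·l,
  where omitted weights are < e⁻³⁰ ≈ 1e-13 of the peak; the truncated
  result matches the untruncated O(n²) double sum to better than 1e-9
  on test grids.  Masked cells contribute to neither numerator nor
  normalization.
- **Trends** are per-pixel OLS slopes with years centred before the
  fit (identical result, better conditioning).  A pixel needs at least
  5 valid annual maps of a decade series (clamped to the series length
  for shorter runs).  Skill metrics (Pearson R, RMSE, bias =
  mean(model) − mean(obs)) are computed after block-averaging both
  trend fields to a coarser grid — factor 10 takes the 5 km grid to
  50 km — over cells valid in both.
- **QA filtering** rejects pixels whose bad-quality percentage
  *strictly exceeds* the threshold (12.5% by default); the boundary
  value is retained.
- **Seeding**: every stochastic element (perturbed-physics draws,
  cover noise, fixture generation) derives from explicit integer seeds
  via `numpy.random.default_rng` seed sequences, with per-(member,
  year) substreams so ensemble members are independent and
  order-insensitive.  Identical seeds give bit-identical outputs.

## Ensemble machinery

Stage 1 is a full factorial over the most uncertain parameters — six
parameters at three levels each gives 729 members — scored against an
observed (or synthetic-truth) trend field and ranked by best
correlation, minimum |bias| or minimum RMSE.  Stage 2 sweeps each of
twelve parameters one at a time over five values around the stage-1
best member (60 base runs); combined with the {deterministic, ±10%
perturbed physics, stochastic cover noise, both} variants this yields
240 sensitivity runs.  Perturbed-physics draws are uniform within
±10%, redrawn annually.  The stochastic cover perturbation is
multiplicative Gaussian, clamped to [0, f_t]; its amplitude is
configurable with a default σ = 0.02 (about the year-to-year retrieval
noise of percent-tree-cover products).

## Synthetic landscapes

`make_synthetic_landscape` generates all model inputs
programmatically: a smooth random cover field (mean 0.70, clipped to
[0, 0.86]) degraded along roads and around towns, domain-crossing
road/river polylines, buffered-point park and concession polygons, a
population field of exponential town kernels (peaks of a few hundred
people km⁻², 12 km decay), and a QA layer with a few rejected patches.
It emulates the *structure* of the real inputs — co-registered
drivers, realistic dynamic ranges, spatial correlation between cover
and access — but not their empirical spatial statistics: passing tests
demonstrate the machinery (conservation, allocation proportionality,
ranking, determinism), not skill against real satellite-derived cover
change, which requires the real driver datasets.

## Experiment sizes

Desk-scale defaults keep every check cheap: conservation is exercised
on a 128×128 grid (one annual step), oracle equivalence on 20×20
grids, and the parameter-recovery experiment on 48×48 landscapes over
5 years at M = −0.005 yr⁻¹ (large enough that five steps produce a
trend clearly above the σ = 0.02 truth noise).  Recovery uses a 3×3
factorial over (k_frag, k_pop) containing the true values and counts a
success when the true member attains the top spatial correlation.

## Known limitations

- Static driver maps: no road-network or population growth over the
  integration.
- Only the forest ↔ replacement transition is tracked; no wood-harvest
  accounting or multi-class land transitions.
- Reforestation is a single relaxation law; it does not distinguish
  clearance causes (shifting agriculture vs. permanent conversion)
  beyond the population discount.
- Rasters are NetCDF only and vectors GeoJSON; reprojection between
  CRSs is out of scope (inputs are assumed on a common lat-lon grid).
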