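# Methods

## The cumulative-impact model

The index follows the additive cumulative-impact tradition for marine
regions, extended with two behavioural factors. Per grid cell,

    CI = (1 − mscf) · Σ_t I_t + mscf · max_t I_t,
    I_t = s_t · rf( M_t ) · d_t,

summing over every (use, pressure, component) sensitivity relationship t.
Assumptions inherited from that tradition: impacts are static (one
reference period, no seasonal dynamics), the response of a component to a
pressure is homogeneous in space, and pressures propagate isotropically —
there is no hydrodynamic transport model behind the spreading.

**Pressure spreading (M).** The normalized use-intensity layer is
convolved with a unit-sum 2D Gaussian kernel. The expert-elicited
"pressure distance" D ∈ [0, 50] km is mapped to the kernel width as
σ = D/3, truncated at radius ⌈3σ⌉ cells, so the elicited distance is the
effective (~3σ) reach of the pressure; the divisor is configurable
(`sigma_divisor`, e.g. 2 for a fatter kernel). Distances below half a cell
collapse to the 1×1 identity kernel. The kernel sums to one so convolution
redistributes rather than inflates intensity; the domain boundary is
zero-padded (an open-sea boundary: intensity may leak out). The convolved
layer is rescaled to [0, 1] by its maximum before the response transform,
so the response function's domain is well defined; consequently only the
relative pattern of a use's footprint matters, not its absolute scale.

**Response (rf).** rf(x) = (1 − NR)·x + NR·L(x), with L a logistic with
inflection at SR, affinely renormalized to L(0) = 0, L(1) = 1. NR ∈ [0, 1]
interpolates linear → threshold behaviour; SR ∈ [0.3, 0.7] places the
threshold along the pressure axis. The logistic steepness is fixed at 10
(slope scale; the sigmoid transitions over roughly ±0.3 around SR), a
choice made because only the endpoints of behaviour and the skewness range
are specified by the elicitation design; it is a constructor argument
(`ResponseParams.steepness`) for anyone wanting a sharper threshold.

**Combination (mscf).** mscf = 0 is the additive model, mscf = 1 the
dominant (maximum) model; intermediate values blend linearly. Mitigative
(negative) combination is deliberately excluded — the sampled range in the
uncertainty analysis is U(0, 1), additive → dominant.

**Normalization.** Use and component layers are normalized to [0, 1] at
load time, linearly (divide by the maximum) or logarithmically
(log(1+x)/log(1+max)) for heavy-tailed intensity data such as shipping
density. A layer whose maximum is exactly 1 is treated as already
normalized and passed through, which makes normalization idempotent in
both modes; the corner case of raw data with maximum exactly 1 that
*should* be log-compressed must be scaled by the caller first.

**Nodata.** Nodata is a boolean mask on the grid, excluded from all sums,
percentiles and index denominators. Rasters travel as single-band float32
TIFF with NaN nodata and a JSON sidecar carrying origin, cell size and
role; no CRS handling beyond requiring all rasters to share one grid.

**Contribution statistics.** Per use: presence% (cells with nonzero
intensity / valid cells), impacted% (cells where any of its impact layers
exceeds a footprint threshold, default 10⁻⁶ of the stack maximum — the
threshold exists only to ignore numerically negligible convolution tails),
and score% (share of the summed impact). Per component: the impacted share
is taken among the cells where the component is present, so impacted% =
100 means impacted across its entire coverage.

## Spatial uncertainty indicators

**DAI** — per cell, the mean (default) or raw count of datasets whose
declared gazetteer regions contain the cell center. Mean mode implements
the published averaging formula and is bounded by 1; sum mode is provided
because figure-style reporting of raw dataset counts is common. Cell
membership is a center-point-in-polygon test (shapely); an any-overlap
variant would differ only along region boundaries.

**LSCI** — per cell, Σ c·I / Σ I over all relationships contributing
impact at the cell, with c the expert confidence. Cells with zero summed
impact are nodata (no confidence information). The index is invariant to a
uniform rescaling of all impacts and bounded by the min/max confidence of
the contributing relationships.

## Uncertainty matrix and semi-quantitative scoring

Sources of uncertainty are classified by location × level × nature
(Walker typology). Each source scores level-weight × nature-weight with
defaults statistical/scenario/ignorance → 1/2/3 and epistemic/variability
→ 1/3, giving the six magnitude types {1, 2, 3, 3, 6, 9}; a sub-location's
score is the sum over its recorded sources (each source counted once).
The weights are configurable (`MagnitudeWeights`) since the elicitation
literature specifies the 1–3 scoring but not a unique product table.
The packaged fixture reconstructs the structure of a published regional
case study (5 locations, 17 sub-locations, 31 sources) from its narrative
description; it is an editable stand-in for testing and demonstration,
not a verbatim copy of the original survey tables.

## Global uncertainty and sensitivity analysis

**Target function.** The CI map of each run divided by that run's domain
maximum ("relative CI"), so the analysis addresses the spatial pattern of
impact rather than its absolute scale; the CV is insensitive to this
choice up to a common run scale.

**Factor groups.** Four groups, sampled and permuted as blocks so the
estimated indices are group-level: SC (one beta factor per top-m triple of
the baseline ranking, mode at the elicited score), D (likewise on
[0, 50] km), MSCF ~ U(0,1), RF = (NR ~ U(0,1), SR ~ U(0.3, 0.7)).
Default top-m = 60; triples outside the top keep their elicited point
values. Groups can be pinned at baseline values (degenerate distributions)
for factor-recovery experiments.

**Beta from mode and confidence.** α = 1 + m(κ−2), β = 1 + (1−m)(κ−2)
with κ = 2 + c·K. The mode equals the elicited value whenever κ > 2 and
the variance decreases strictly with confidence; c = 0 gives the uniform
(a maximally uninformative expert). Default K = 18, so full confidence
corresponds to concentration κ = 20 (sd ≈ 0.1 around a central mode) —
a deliberate calibration point: confident experts are taken to be sure to
about ±1 scoring step on a 0–1 scale.

**Design.** Saltelli radial design at cost N(2k+2): matrices A and B from
a scrambled Sobol' sequence of dimension 2·dims, plus per-group radial
blocks AB_g (A with group g's columns from B) and BA_g. k = 4 groups, so
N = 1500 reproduces the reference cost of 15,000 model runs. Marginals are
realized through each factor's inverse CDF. The same seed always yields
the same matrix.

**Estimators.** Per cell: S1 by the Saltelli-2010 first-order estimator
mean(f_B·(f_AB − f_A))/V; ST by the Jansen estimator
mean((f_A − f_AB)²)/(2V); S2 by the closed Saltelli-2002 estimator
mean(f_BA_i·f_AB_j − f_A·f_B)/V − S1_i − S1_j. These are the standard
robust choices. Cells with zero output variance are nodata. Negative
estimates (Monte Carlo noise around small true values) are reported
as-is and should be clipped only for display. Validation: on the Sobol'
g-function with a = (0, 0.5, 3, 9) at N = 2¹³ the estimates land within
0.02 of the analytic indices, and they agree with a brute-force
double-loop conditional-variance decomposition within 0.03 at matched
cost (both are tests in the suite).

**UA summaries.** Per cell over the ensemble: mean, coefficient of
variation (population sd / mean, nodata at zero mean), and exceedance
frequencies — for each run, cells strictly above that run's 75th (90th)
linear-interpolation percentile over valid cells are "most impacted",
below the 25th (10th) "least impacted"; the maps give the fraction of runs
so flagging each cell. All summaries are invariant under a positive
rescaling of the whole ensemble.

## Synthetic study cases

`make_case` generates the full input set a regional assessment needs:
sparse use footprints (points, corridors, patches) with log-normal(0, 1)
intensities before normalization, mirroring the heavy-tailed character of
maritime-activity data; fixed components as binary habitat patches and
mobile components as smooth 0–1 presence-probability surfaces (about a
third of components mobile by default); a sensitivity table over a random
subset of triples with scores/confidences in [0, 1] and distances in
[0, 50] km; a gazetteer partitioning the domain into strips with
per-dataset coverage declarations; and the packaged uncertainty matrix.
Defaults are a 100×100 grid at 1 km with 15 uses and 31 components — a
desk-scale stand-in for a regional sea grid of ~300,000 cells with a
realistic dataset inventory. Everything is reproducible from the seed.

What the generator does **not** emulate: real coastline geometry and
bathymetry, spatial correlation between uses and habitats (ports near
shipping lanes), anisotropic pressure transport, and expert scores with
structured disagreement. Passing tests on synthetic cases therefore
validate the machinery — estimator correctness, determinism, closed-form
identities — not the ecological realism of any particular map.

`make_known_truth_case` builds three analytically predictable cases:
`single_driver` (two overlapping distance-0 impacts; with only MSCF
sampled the per-cell output is a deterministic function of mscf, so
S1_MSCF ≈ 1 at overlap cells), `additive_pair` (closed-form ratio
CI(mscf=0)/CI(mscf=1) = (I₁+I₂)/max(I₁,I₂)), and `mscf_sensitive`
(a mid-intensity impact whose response swings with SR co-occurring with a
stable high-intensity one, plus a dedicated anchor use pinning the domain
maximum so the per-run rescaling is constant; the product structure
(1 − mscf)·rf-term leaves per-cell ΣS1 ≈ 0.85–0.93, a detectable
interaction signal).

## Problem sizes and numerical conventions

Test and demonstration runs use deliberately small problem sizes chosen so
the statistical assertions are sharp at desk scale: estimator validation
at N = 2¹³ on scalar functions, factor recovery at N = 256–1024 on 12×12
grids, and the end-to-end determinism check at N = 16 on the default
100×100 case (determinism, not index accuracy, is what that check
establishes). Tie-breaks in triple ranking are lexicographic on
(use, pressure, component). Percentiles are linear-interpolation
percentiles over valid cells. The pipeline manifest records every
convention in effect (σ-mapping, κ-scale, steepness, estimator set,
percentile rule) together with content hashes of all outputs, so a run is
auditable and exactly reproducible from config + seed.

## Known limitations

- No hydrodynamic or anisotropic pressure transport; Gaussian spreading
  only.
- Within-group ranking of individual sensitivity scores is out of scope
  (the group design estimates SC as a whole).
- The post-convolution rescale makes absolute use intensities
  non-identifiable; only relative footprints enter the index.
- GeoTIFF georeferencing is minimal (sidecar JSON, no CRS); reprojection
  must happen upstream.
- The semi-quantitative weight table is a convention; rankings should be
  read ordinally, not cardinally.
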