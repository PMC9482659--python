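# Methods

## Scope and design

`endemia` implements a complete desk-scale version of the ensemble
species-distribution-modelling workflow used to project climate-change
impacts on endemic species, together with a synthetic-world generator that
provides the ground truth real studies lack. The pipeline has six stages —
world generation, occurrence preparation, niche-model fitting, ensemble
projection, biodiversity accounting, climate profiling — each a pure
function of the configuration and a single seed. All randomness flows
through stable sub-seeds (a hash of the top seed with the species id,
replicate index or stream name), so reruns are bit-identical and adding a
species never perturbs another.

## The synthetic world

**Climate.** Nineteen bioclim-style layers are built from smoothed Gaussian
noise: each layer mixes a family latent field (one for the eleven
temperature-type layers, one for the eight precipitation-type layers) with
its own noise, all low-pass filtered to an autocorrelation length of 4 cells
by default. Latent coupling is heterogeneous — the leading layers of a
family share the latent at the configured `cross_corr` (default 0.85),
trailing layers progressively less, down to 20% of it — so pairwise
correlations span a realistic range: the strongest pairs exceed the 0.8
selection threshold (collinearity pruning has real work to do) while the
trailing layers carry quasi-independent signal, as in real bioclim data. A
uniform coupling would make the entire family mutually collinear and
collapse predictor selection to two or three layers, which real corrSelect
runs do not do. Layers are mapped to plausible units (°C, mm) by per-layer
affine transforms; all statistics downstream are invariant to that mapping.

**Scenarios.** Future climates add per-layer drifts expressed in
baseline-standard-deviation units, accumulating linearly over three horizons
(T1–T3 receive 1/3, 2/3, 3/3 of the final drift). Two families are built:
*control* (plain strong warming/drying, default final drift ≈ 2.3σ in
aggregate) and *melting* (the same pattern intensified, ≈ 4.3σ, with extra
drift on maximum temperature of the warmest month, precipitation of the
driest month, and the two seasonality layers — the variables a
freshwater-forcing scenario perturbs hardest relative to plain warming).
Generation validates, and re-asserts on the produced stacks, that the
melting family is strictly more dissimilar from the baseline (mean per-cell
standardized Euclidean distance) than the control family at every horizon;
the downstream "tipping-point" contrast tests are meaningful only because
this ordering is enforced climatically, never assumed biologically. The
default drift magnitudes are comparable to the niche breadths drawn for the
virtual species (σ ≈ 0.5–1.4), placing the control family in the
strong-impact regime that high-emission projections represent, with the
melting family clearly beyond it.

**Countries and ecoregions.** Twelve countries partition the grid by
nearest-seed assignment with ten Lloyd-relaxation iterations (raw random
seeds occasionally produce sliver countries too small to host an endemic
range); each country is subdivided into ecoregions the same way, with
globally unique ecoregion ids nested inside exactly one country. All cells
are land by default; an ocean can be introduced by masking but small
fixtures stay simpler without one.

**Virtual species.** A species' niche is Gaussian in standardized climate
space: suitability(x) = exp(−Σ_v (z_v − μ_v)²/(2σ_v²)) over 2–3 niche
variables, and its true range is the set of in-country cells with
suitability ≥ τ. Three design rules make the drawn species *scientifically*
endemic rather than merely label-clipped, which is what makes range-recovery
a fair test of the modelling machinery:

1. niches combine at least one thermal and one moisture axis, drawn from the
   weakly latent-coupled layers of each family (real climatic constraints
   act through quasi-independent axes, not through near-duplicate derived
   variables);
2. the niche optimum is anchored at the standardized climate of an interior
   country cell (most interior of four candidates), so suitability 1 is
   attained inside the country and ranges are never empty for τ < 1;
3. τ is chosen as the lowest value in the configured range (default
   0.4–0.8, 9-point grid) for which at least 90% of the suitable cells
   grid-wide fall inside the country and the range holds at least 30 cells;
   draws are retried up to 120 times and the most endemic qualifying draw is
   kept if the 90% target is never met, so generation always succeeds.

The 30-cell floor exists because the modelling pipeline only accepts species
with ≥ 25 unique occurrence cells; a generator producing unmodelable species
would test nothing.

**Occurrences.** Records are drawn with replacement from the true range with
probability proportional to suitability (default 300 per species). With
probability `detection_noise` a record is displaced to a uniformly random
cell of the species' country — uniform label noise; there is no spatial
sampling-bias model, so tests passing under noise say nothing about
roadside-bias-style artefacts in real data.

## Data preparation

Records are snapped to cells and deduplicated; species need ≥ 25 unique
cells (configurable) and are capped at a uniform random 500. Endemicity
requires all cells to lie within one country dilated by 0.08333° (converted
to whole cells by ceiling — conservative inclusion; all dilations in the
package are Chebyshev, i.e. square-structuring-element). Predictor
pre-selection runs per species on its calibration cells: while any kept pair
of layers has |r| ≥ 0.8, the member of the worst-offending pair with the
higher OLS variance-inflation factor is dropped (ties drop the later layer).

## Niche models

The calibration region M is the 4° occurrence buffer intersected with the
occupied ecoregions; if |M| ≤ |presences| + 1 (the insular pathology), M
falls back to the whole country. The projected region is M dilated by 2°,
within which full dispersal is assumed. Pseudo-absences are a uniform sample
without replacement from M minus the presence cells, at most 10,000;
presence and absence classes carry equal total weight (prevalence 0.5).
Species whose M cannot support training at all (empty absence pool, or
fewer than 7 cells in a class, too few to stratify ten 70/30 replicates)
are recorded as skipped with a reason and excluded downstream, mirroring how
problem species are handled rather than aborting a whole run.

Five algorithm families share one fit/predict contract (suitability in
[0, 1] anywhere climate is defined), chosen to retain ensemble
heterogeneity at desk scale: a percentile surface-range envelope
(2.5–97.5% presence box, binary score), a penalized logistic regression on
linear + quadratic standardized features (C = 10), a depth-8 classification
tree, an 80-tree random forest with feature subsampling, and a Maxent-style
model fitted by maximizing the presence log-likelihood of a Gibbs
distribution normalized over the background cells (linear + quadratic
features, L2 ridge 0.005, L-BFGS). The parametric models' quadratic features
can represent an ellipsoidal niche boundary exactly; the relatively light
regularization reflects that training sets here are noise-free and label
the calibration region completely, so sharp boundaries are supported — on
noisier real data these constants should be revisited. Feature
standardization uses training-region statistics and is reused unchanged
when projecting onto future climates.

Evaluation: AUC by pairwise concordance with ties counted ½ (computed via
rank sums, oracle-tested against explicit pair enumeration), and TSS
maximized over the threshold grid {0.00, 0.01, …, 1.00}; reported TSS ties
break toward the lowest threshold. Variable contributions are permutation
importances — the drop in training AUC over five seeded shuffles of one
layer, evaluated on a balanced subsample of at most 500 cells per class to
keep per-replicate importances cheap.

## Ensembles and projection

Members with held-out AUC strictly above 0.7 enter the consensus with weight
equal to their AUC. The ensemble is evaluated by scoring every member's
held-out split with the consensus itself and pooling — one evaluation, hence
one threshold, per species. **Binarization threshold:** the pooled scores at
desk scale often separate perfectly, so the TSS-maximizing threshold is a
plateau rather than a point. The low end of that plateau sits directly above
the best-scoring pseudo-absence and systematically sweeps into the binary
range cells of the projected region that the calibration data never covered;
the package therefore binarizes at the *highest* TSS-maximizing grid
threshold — equally TSS-optimal, maximally specific, and immaterial whenever
scores overlap (as they do on real data). Future projections reuse the
present-day weights and threshold; re-thresholding on future data is
impossible without future truth. Cross-algorithm agreement is the per-cell
coefficient of variation (sample SD / mean, cells with mean < 10⁻⁶ are
no-data) across per-algorithm consensus maps. Note that with a binary-scoring
envelope among five members, desk-scale CV values are much larger than those
of large real ensembles averaging hundreds of smooth maps.

## Biodiversity accounting

Range change is (n_future − n_present)/n_present on binary maps over the
projected region; −1 is complete loss. The five reporting categories are
closed on the loss side: complete loss (= −1), severe (−1, −0.5], moderate
(−0.5, 0), stable/gain [0, 0.5], strong gain (> 0.5); the edges are
configurable since the category scheme is a reporting convention, not a
measurement. PAMs stack binary maps over the full grid; SR is the column
sum (the conservation identity Σ_cells SR = Σ_species range size is tested
exactly); ΔSR = SR_future − SR_present, so positive values are gains — note
that the alternative current-minus-future orientation appears in parts of
the literature, and the sign is stated here once to avoid ambiguity. PSH
are cells with SR strictly above 0.6 × the per-country present-day maximum
SR (0.2 and 0.9 as sensitivity variants); the absolute cutoff is frozen
from the present day and applied to future SR maps, because re-deriving
maxSR from a shrinking future map would conflate richness decline with
threshold drift. Temporal β_SØR = (b+c)/(2a+b+c) per cell; cells empty in
both periods are no-data; the PSH summary is the median over present-day
hotspot cells (pooled globally, also available per country). No
turnover/nestedness decomposition is computed.

## Climate profiles

Scenario deltas summarize per-cell future − baseline differences (mean and
linear-interpolation quartiles) for annual mean temperature, annual
precipitation, max temperature of the warmest month and precipitation of the
driest month. Gain/loss profiles characterize the present-day climate
(annual mean temperature, temperature seasonality, annual precipitation,
precipitation seasonality) of cells with ΔSR strictly above its third /
below its first quartile, quartiles taken over the cells where richness is
defined (zeros included). The two variable lists differ deliberately —
deltas profile what the scenarios change, gain/loss profiles what kind of
climate wins or loses richness — and both are configurable. If no cell
exceeds the quartiles (a flat ΔSR field), the profile raises rather than
returning empty summaries.

## Numerical and formatting choices

Grids are regular lon/lat rasters; cell centers and indices round-trip
exactly. Rasters are written as ESRI ASCII grids — a plain-text format every
GIS reads — with `repr`-precision floats so reruns are byte-identical;
tables are CSV; the run manifest is JSON (sorted keys, no paths or
timestamps). The default study grid is 60×60 cells of 0.5°, making countries
several degrees wide so that the 4°/2°/0.08333° buffers of the method keep
their intended proportions at desk scale; the resolution is fully
configurable. The 20×20-cell smoke configuration lowers the unique-record
floor to 10 because 25-cell ranges do not reliably fit a 400-cell world;
every other constant keeps its standard default.

## Problem sizes

Default study runs (30 species, 60×60 grid, 5 algorithms × 10 replicates,
7 climate stacks) complete in roughly two to three minutes on one CPU; the
smoke configuration in ~20 s. These sizes were chosen so that the full
recovery and scenario-ordering experiments are routine to rerun while still
exercising every code path of the method.

## Known limitations

- Virtual species have hard-threshold Gaussian ranges and noise-free-by-default
  occurrences; recovery results bound what the pipeline can do under ideal
  detection, not what it will do on biased real data.
- The synthetic "melting" family is a scalar intensification of the control
  drift pattern, not a circulation-model experiment; only the enforced
  dissimilarity ordering, not the spatial pattern of change, is meaningful.
- Pseudo-absences never coincide with presence cells, a choice that avoids
  label conflict but sharpens class separation relative to random background
  sampling.
- Ensemble membership is gated on AUC; gating on TSS instead can change
  member sets for weakly discriminating species.
- The alternative consensus rules (median, committee averaging) are not
  implemented; the consensus is always the AUC-weighted mean.
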