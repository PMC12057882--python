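# Methods

This note documents the models implemented in `oasisrisk`, the choices
made where the methodology is genuinely open, and what the synthetic
test bed does and does not establish about real data.

## Zonation

NDVI is thresholded into three belts: oasis (NDVI ≥ `oasis_min`,
default 0.30), desert (NDVI ≤ `desert_max`, default 0.10), transition
otherwise. Both boundary values are assigned inclusively (0.30 → oasis,
0.10 → desert); the two tie-break choices are otherwise arbitrary, so
they are fixed and documented here. Thresholds are stored as fractions;
`ZoneThresholds.from_percent` parses percent notation. Reference sample
points are point-in-cell lookups (0-based row/col, origin top-left,
nearest cell centre, no interpolation).

Accuracy statistics follow the remote-sensing convention:
OA = trace/total, κ = (OA − p_e)/(1 − p_e) with
p_e = Σ row_i·col_i / total², UA_i = diag_i/rowsum_i,
PA_i = diag_i/colsum_i. OA and κ are orientation-invariant; UA/PA
orientation is configurable (`rows-map` default) because published
accuracy tables do not always state whether rows are the map or the
reference, and the two conventions swap UA with PA. An empty row or
column yields NaN for the affected accuracy, never 0.

## Landscape indices and ERI

Per landscape type *i* over total mapped area *A* (km², nodata
excluded), with N_i patches and area A_i:

- C_i = N_i / A_i (fragmentation, patches per km²)
- S_i = (A / 2A_i) · √(N_i / A) (separation). The separation index
  appears garbled in parts of the applied literature; the standard form
  above is adopted because it is dimensionally consistent and monotone
  in the quantities it is meant to reflect (more patches ⇒ more
  separated; larger type area ⇒ less separated).
- D_i = (Q_i + M_i)/4 + L_i/2 (dominance), Q_i = fraction of sampling
  cells where the type occurs, M_i = N_i / ΣN_j, L_i = A_i / A. Bounded
  by 1, attained by a monoculture.
- LDI_i = a·C_i + b·S_i + c·D_i with (a,b,c) = (0.5, 0.3, 0.2) for
  utilized land and (0.3, 0.2, 0.5) for unutilized land. Of the seven
  land-use classes, only unused land is flagged unutilized.
- LFI_i: vulnerability ranks built-up 6, forest 5, cropland 4,
  grassland 3 (both coverage classes share the rank), water 2,
  unused/desert 1, sum-normalized so Σ LFI_i = 1.

Indices are computed **globally per type per epoch**, not per sampling
cell: the dominance term Q_i is defined over the full set of sampling
cells, which makes it a global quantity, and a global index table keeps
ERI differences between cells interpretable as pure composition
effects. The per-cell alternative found in parts of this literature
would conflate composition with local patch geometry.

ERI_k = Σ_i (A_ki/A_k)·LDI_i·LFI_i on square sampling cells (1 km
default). As a convex combination it satisfies
0 ≤ ERI_k ≤ max_i LDI_i·LFI_i; composition closure Σ_i A_ki = A_k holds
by construction (asserted at 1e-6 km²). Cells with less than 10 % of
their nominal area inside the study area are dropped — boundary slivers
otherwise produce compositions dominated by a handful of pixels.

Patch delineation uses 8-connectivity by default (diagonal adjacency
merges, the common remote-sensing convention); 4-connectivity is
available. Risk levels are equal-interval breaks over the pooled
min–max of all epochs supplied together, so one shared break set makes
levels comparable across epochs; the break method in applied studies is
frequently unstated, and equal intervals are the reproducible default.
A constant ERI field yields a single level with a warning. Inverse-
distance-weighted interpolation (power 2) of cell values is provided
for map display only; all analysis uses raw cell values.

## Spatial autocorrelation

Global Moran's I and the local decomposition follow the classical
formulas (see `spatial.py`); Σ_i I_i / S0 = I holds exactly and is
asserted at 1e-9. Weights are queen contiguity, row-standardized by
default — the defaults of the mainstream exploratory spatial analysis
tools — with rook and binary variants available. Inference is by
conditional permutation (hold x_i, redraw its neighbours from the
remaining cells), 999 permutations, α = 0.05, seeded; the pseudo-p is
the folded one-tail proportion of permuted statistics at least as
extreme as the observed one. Cluster labels (HH/HL/LH/LL) come from the
sign quadrant of the cell's deviation and its spatial lag and are only
assigned where pseudo-p ≤ α. Islands (cells with no neighbour) keep a
zero lag and are never significant.

## Change accounting and scenarios

Cross-tabulation counts cells jointly valid in both epochs; flows are
cell counts × cell area. Markov estimation is row normalization of the
flow matrix; a class absent at t0 gets an identity (full persistence)
row with a warning, since an unsourced class has no estimable outflow.
Projection iterates areas_{t+1} = areas_t·P at the calibration step
(decadal for decadal inputs) and conserves total area to rounding.

Scenario rules multiply targeted transition **probabilities** (not
areas — equivalent up to the renormalization rule, and probabilities
are what the projection consumes). After adjustment the diagonal
(persistence) entry absorbs the difference, which is the
least-distorting way to restore row-stochasticity: restricting a
transfer means the land stays put. If persistence would go negative the
whole row is rescaled proportionally with a warning; an adjusted entry
exceeding 1 is clipped with a warning. The bundled government scenario
applies ×0.8 to vegetated→{built-up, unused}, ×1.3 to
unused→vegetated, and ×1.1 to built-up→{forest, grassland}, where
"vegetated" is cropland, forest and both grassland classes.

## Driver analysis

The regressor is a bootstrap ensemble of regression trees with
per-split random feature selection, i.e. a random forest, built on
`BaggingRegressor` so that each tree's bootstrap rows — and hence its
out-of-bag (OOB) rows — are public, which the importance score
requires. The importance of predictor j is
IS_j = mean over trees of (errOOB2 − errOOB1), where errOOB1 is the
tree's OOB mean squared error and errOOB2 the same after interference
on predictor j. Interference is a within-OOB permutation by default
(the standard operationalization of "random noise interference"); an
additive-Gaussian variant is behind `method="noise"`. The mean over
trees (rather than the bare sum) is used so the score does not scale
with ensemble size. Reported relative influence clips negative raw
scores at zero and normalizes to sum 1.

Predictors are min–max normalized with bounds from the training rows
only; the seeded split defaults to 484/646 training rows (exactly
484/162 at n = 646). Hyperparameters are tuned by exhaustive grid
search with 4-fold cross-validation on the training rows. The default
grid (n_estimators {10,20,30,40,50}, max_depth {3,6,10,15,20},
max_features {2,4,6,8}) spans the useful range while tuning in minutes;
the exhaustive unit-step grid over n_estimators 5–50, max_depth 1–20,
max_features 1–9 is available as `FULL_GRID`.

Evaluation: R² = 1 − SSE/SST (the conventional coefficient of
determination — a ratio with predictions in the numerator sum is
sometimes printed in applied work but is not a goodness-of-fit
measure), RMSE = √(SSE/n), RPD = √SST/√SSE with categories
excellent (≥2), fair (1.4–2), low (<1.4). Since both are built from
the same sums, RPD = 1/√(1−R²) identically when R² < 1; a perfect fit
reports RPD = +∞, category excellent.

## Synthetic landscapes

The generator emulates the structure the analysis assumes, at the
study's design points: a radial NDVI profile v(d) = v0·exp(−λd)
(monotone, so every threshold is crossed exactly once and zonation
recovers concentric rings; v0 = 0.6 puts the core firmly in the oasis
regime), Gaussian NDVI noise (default sd 0.02, a typical Landsat
NDVI repeatability scale), seven land-use classes evolving by a
per-cell Markov chain over ≥2 decadal epochs, and driver tables of
nine predictors at n = 646 with planted effects (dominant 1.0 on
distance-to-towns, secondary 0.5 on population, the rest pure noise)
plus response noise sd 0.05. Each top-level generator draws from its
own deterministically derived sub-stream of the config seed, so
regenerating one product never shifts another, and equal seeds give
bit-identical outputs.

The optional 3×3 majority filter creates contiguous patches but is a
spatial interaction the Markov chain does not model, so it is disabled
whenever empirical transition frequencies must recover the planted
matrix (recovery is tested at 200×200 cells, max entry error < 0.02).

What the synthetic bed does **not** emulate: Landsat radiometry and
cloud/atmosphere artefacts, spatially autocorrelated driver surfaces,
socio-economic realism, or the patch-level spatial allocation of
projected demand (projections here are areal class totals). Passing
tests therefore establish the correctness of the computations and
their contracts, not the field validity of any particular threshold or
weight choice; published headline statistics that depend on the real
rasters (global Moran's I values, per-epoch ERI thresholds, projected
2030 risk shares, real-data R²) are out of reach by construction and
only the formulas behind them are verified.

## Numerics and degenerate inputs

- Areas in km²; cell size from the raster header; half-open pixel
  convention with origin top-left.
- ASCII-grid round trips are bit-exact for integer rasters, float32 for
  continuous; plain TIFF carries no georeferencing, so a missing cell
  size falls back to 1 m with a warning (ASCII grid is the
  georeferenced text format of record here).
- Constant fields: Moran statistics raise (undefined); risk-level
  classification warns and assigns one level; a constant predictor
  normalizes to 0 with a warning.
- Moran on a checkerboard with rook row-standardized weights is −1
  exactly; this closed form anchors the implementation.
- Problem sizes in tests and the acceptance script (20×20 oracle
  rasters ×100, 200×200 Markov recovery, 8×8 Moran lattice with 999
  permutations, 646-row driver tables ×20 replicates, 30×30 risk
  landscapes ×50) are chosen so each statistical check has comfortable
  resolution at its stated tolerance while the whole suite runs in
  well under a minute of compute per module.
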