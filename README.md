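# oasisrisk

Landscape ecological risk analysis for oasis-desert cities.

Arid-zone settlements are organised as concentric belts — a vegetated
oasis core, a sparse transition belt, and surrounding desert — and their
rapid development reshapes that structure in ways that can degrade
fragile ecosystems. `oasisrisk` implements the standard analysis chain
used to quantify that risk from multi-epoch remote-sensing products:

1. **Zonation** — NDVI thresholding (oasis ≥ 0.30, desert ≤ 0.10,
   transition between) with confusion-matrix accuracy scoring (overall
   accuracy, Cohen's κ, user's/producer's accuracies).
2. **Ecological risk index (ERI)** — for each landscape type *i*:
   fragmentation C<sub>i</sub> = N<sub>i</sub>/A<sub>i</sub>, separation
   S<sub>i</sub> = (A/2A<sub>i</sub>)·√(N<sub>i</sub>/A), dominance
   D<sub>i</sub> = (Q<sub>i</sub>+M<sub>i</sub>)/4 + L<sub>i</sub>/2,
   disturbance LDI<sub>i</sub> = a·C<sub>i</sub> + b·S<sub>i</sub> + c·D<sub>i</sub>
   with weights (0.5, 0.3, 0.2) on utilized and (0.3, 0.2, 0.5) on
   unutilized land, and sum-normalized vulnerability ranks LFI<sub>i</sub>.
   On a 1-km sampling grid each cell's risk is the composition-weighted
   product ERI<sub>k</sub> = Σ<sub>i</sub> (A<sub>ki</sub>/A<sub>k</sub>)·LDI<sub>i</sub>·LFI<sub>i</sub>.
3. **Spatial autocorrelation** — global Moran's I and local (LISA)
   statistics with conditional-permutation inference and
   High-High/High-Low/Low-High/Low-Low cluster typing.
4. **Change and scenarios** — cross-tabulated area-flow matrices,
   signed percent change, Markov-chain estimation and areal projection,
   and policy scenarios as multiplicative adjustments to targeted
   transition probabilities (bundled government-regulation scenario:
   ×0.8 vegetated→built-up/unused, ×1.3 unused→vegetated,
   ×1.1 built-up→forest/grassland).
5. **Driver importance** — a bagged regression-tree ensemble with
   out-of-bag permutation importance
   IS<sub>j</sub> = mean<sub>t</sub>(errOOB2 − errOOB1), tuned by grid
   search with 4-fold cross-validation and scored by R², RMSE and
   RPD = 1/√(1−R²).

A synthetic-landscape generator produces NDVI fields, land-use series
driven by a known Markov chain, and driver tables with planted effect
sizes, so the entire chain runs and is testable with no external data.

## Worked example

```python
import oasisrisk as ok

cfg = ok.SyntheticConfig(grid_shape=(120, 120), cell_size=250.0, seed=7,
                         radial_decay=0.03, noise_sd=0.02, n_epochs=2)
zones = ok.classify_zones(ok.generate_ndvi(cfg))
print(ok.zone_areas(zones).round(2).to_dict())
# {'oasis': 106.94, 'transition': 584.12, 'desert': 208.94}

lu0, lu1 = ok.generate_landuse_series(cfg)
grid = ok.build_risk_grid(lu1, grid_size_m=1000.0)      # 900 sampling cells
grid = ok.eri(grid, ok.landscape_indices(lu1, grid))
# per-cell ERI: mean 0.0608, range 0.0145-0.1210

w = ok.build_weights(grid)                               # queen, row-standardized
res = ok.local_moran(grid.cells["eri"].to_numpy(), w, seed=7)
# global Moran's I = 0.3864 (null expectation -0.0011):
# neighbouring cells carry similar risk far beyond chance;
# 89 cells type as High-High clusters, 120 as Low-Low

M = ok.estimate_markov(ok.cross_tabulate(lu0, lu1, labels=ok.LAND_CLASSES))
areas = ok.cross_tabulate(lu0, lu1, labels=ok.LAND_CLASSES).areas_t1()
nat = ok.project_areas(areas, M)
gov = ok.project_areas(areas, ok.apply_scenario(M, ok.GOVERNMENT_SCENARIO))
# one decadal step: built-up 115.28 km^2 natural vs 114.17 km^2 under
# regulation; unused land 126.29 vs 123.86 (restoration redirects it)

table = ok.normalize_and_split(ok.generate_driver_table(cfg, 646), seed=7)
report = ok.fit_and_validate(table, seed=7)
# validation R^2 = 0.892, RMSE = 0.0801, RPD = 3.05 ("excellent");
# normalized importance: distance_to_towns 0.78, population 0.21 —
# the two planted drivers, recovered in the planted order
```

The same stages are available from the shell:

```sh
oasisrisk generate --seed 7 --outdir demo
oasisrisk zonate --ndvi demo/ndvi.asc --out demo/zones.asc
oasisrisk risk --landuse demo/landuse_3.asc --grid-size 1000
oasisrisk drivers --table demo/drivers.csv --seed 7
oasisrisk run --config pipeline.yaml        # full multi-epoch pipeline
```

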