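# nicheshift

Climatic niche-shift analysis for invasive plants: has an invader's
realized climatic niche changed between its native and introduced
ranges, and does that change line up with the species' physiology?

`nicheshift` re-implements, as a tested and reusable Python pipeline,
the standard analysis chain used to answer that question from
presence-only occurrence records (GBIF-style CSVs) and gridded
bioclimatic layers:

1. **Occurrence preparation** — coordinate validation, greedy spatial
   thinning at a minimum haversine distance (default 1 km), and
   extraction of every climate layer at each record's raster cell.
2. **Environmental ordination (PCA-env)** — a correlation-matrix PCA
   calibrated on the pooled *available* climates (backgrounds) of both
   study regions; occurrences are projected into the first two
   components.
3. **Occupancy and overlap** — each range's occurrence cloud becomes a
   kernel-smoothed density on a shared R×R grid of the PCA plane,
   corrected for climate availability (density ratio *o/e* at a common
   bandwidth) and normalized. Overlap between ranges is Schoener's

   D = 1 − ½ Σᵢⱼ |z₁(i,j) − z₂(i,j)| ∈ [0, 1],

   and the invasion is decomposed within analogous climates into niche
   **stability**, **expansion** and **unfilling**.
4. **Permutation tests** — the *equivalence* test pools and randomly
   reallocates occurrences between ranges (sizes fixed) to ask whether
   the observed D could arise from one shared niche; the *similarity*
   test relocates one range's whole occupancy at random within its
   background to ask whether the overlap exceeds chance.
5. **Reciprocal suitability models** — a presence–background
   maximum-entropy model in its penalized-GLM form (L1 logistic
   regression on linear + quadratic features, 5-fold presence CV, AUC),
   projected reciprocally; contrasting the two projections on the
   introduced region yields the **increased introduced suitability**

   100 × Σᵢⱼ(δ_introduced − δ_native) / Σᵢⱼ δ_introduced,

   with a fold-ensemble mean ± SEM.
6. **Physiology–performance links** — a "performance" statistic (a
   range's relative occurrence density along bio11, the mean temperature
   of the coldest quarter, interpolated at experimental sampling
   temperatures) is linked to leaf physiological markers (hydration,
   chlorophyll fluorescence, pigments, tocopherol; including the exact
   forms DPS = (Zx+Ax)/(Vx+Ax+Zx) and H = (FW−DW)/DW) with
   random-forest classification and regression.

Because real GBIF/WorldClim snapshots are external and version-dependent,
the package ships a first-class **virtual-species simulator**: spatially
autocorrelated bioclim rasters built from shared latent temperature and
moisture fields, presence samples drawn from a known Gaussian niche
(optionally shifted between ranges, optionally with sampling bias), and
physiological marker tables with range × temperature means. Every
downstream stage is validated against this known ground truth.

## Worked example

```python
import numpy as np
import nicheshift as ns

# A two-range scenario: 52 native and 492 introduced occurrences, with
# the introduced niche shifted 2 SD toward colder annual temperature.
cfg = ns.ScenarioConfig(seed=1)
scen = ns.make_shift_scenario(cfg)

bg_nat = scen.grid_native.env_table()
bg_int = scen.grid_introduced.env_table()
space = ns.calibrate_env_space(bg_nat, bg_int)
extent = ns.grid_extent(np.vstack([space.transform(bg_nat),
                                   space.transform(bg_int)]))
z_nat = ns.occupancy_grid(space, scen.occ_native, bg_nat, 100, extent)
z_int = ns.occupancy_grid(space, scen.occ_introduced, bg_int, 100, extent)

dyn = ns.niche_dynamics(z_nat, z_int)
eq = ns.equivalence_test(scen.occ_native, scen.occ_introduced, space,
                         bg_nat, bg_int, n_iter=99, seed=1)
print(f"D = {dyn.D:.3f}  expansion = {dyn.expansion:.3f}  "
      f"unfilling = {dyn.unfilling:.3f}  equivalence p = {eq.p_value:.3f}")
```

Output:

```
D = 0.254  expansion = 0.544  unfilling = 0.460  equivalence p = 0.010
```

The shifted niche overlaps its native counterpart by only D ≈ 0.25;
about half of the introduced occupancy sits in climates the native
niche does not use (expansion), and equivalence is rejected
(p = 0.01 at 99 permutations). With `shift_magnitude=0` the same
pipeline returns D = 0.557 for this seed and a non-significant
equivalence test.

The same analysis runs from the command line:

```bash
nicheshift run --config run.yaml --out results/
nicheshift prep --occ records.csv --rasters rasters/ --min-dist-km 1.0 --out clean/
```

`run` writes cleaned occurrences, PCA loadings, occupancy grids, a
comparison JSON (D, dynamics at the 100% and 75% analog levels, both
permutation tests), suitability summaries, link-model results, and a
manifest with every seed and a hash of the numeric outputs (reruns are
byte-identical).

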