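# nfert

Reconstruction pipeline for gridded, crop-specific nitrogen fertilization:
annual N application **rates** (synthetic fertilizer, manure, crop residues),
**fertilizer-type** shares (13 types), and **placement** fractions
(surface vs deep) on a regular lon/lat grid, 1961–2020.

Land-surface and nutrient-cycling models (DNDC-style biogeochemistry, NH₃
emission and N₂O upscaling models) need to know not just *how much* nitrogen
reached cropland, but *which crop received it, in what chemical form, and
whether it was incorporated into the soil*. National statistics carry none
of that spatial or agronomic detail. `nfert` implements, as a tested and
reusable library plus CLI, the allocation machinery that turns national
statistics and a handful of reference maps into such a dataset — and a
synthetic-world generator with known ground truth so every stage can be
verified offline, without downloading any real input.

## The model

Everything hangs on one factorization of the N amount applied to crop *cro*
with fertilizer type *f* and placement *p* in grid cell *g* and year *y*:

```
Namount(cro,f,p,y,g) = Harea(cro,y,g) · Nrate(cro,y,g) · FerRatio(f,y,g) · Placement(cro,f,p,y,g)
```

Each factor is reconstructed by its own stage:

1. **Harvested area** — a year-2000 county reference map is extended through
   time with national ratios (counties track their country), re-attributed
   across political disintegrations by first post-split shares,
   disaggregated to cells in proportion to cropland (a rice layer for rice,
   upland for everything else), and rescaled so national sums match the
   statistics exactly.
2. **Rates** — county N amounts by class (SN/MA/CR) from a prior product
   are extended to 2020 with national ratios, SN is corrected to national
   statistics, and amounts are split across the 21 crop groups under the
   *constant-ratio assumption*: all crops in a county share one temporal
   scaling of the rate, anchored on a year-2000 crop-specific rate map.
   Rates after 2003 are calibrated to crop-group consumption surveys (FUBC,
   anchor years 2006/2007/2010/2014/2018).
3. **Type shares** — survey consumption of 11 synthetic types (with its
   structural 1962–1972 gap filled by bootstrap-EM multivariate-normal
   imputation over log consumption, covariates, and time polynomials) is
   combined with the class amounts into 13 shares that sum to one.
4. **Placement** — a gridded no-till surface is built from a national
   adoption regression (cropland per rural capita), census statistics where
   available, an eligibility screen (11 rain-fed annual crops; field-size
   and income rules), a four-predictor logit probability, and greedy ranked
   allocation.  Injected fertilizers are fully deep; other synthetic types
   are deep at `0.7 × NoTill`; manure and residues at `1 − NoTill`.
5. **Uncertainty** — Monte Carlo perturbation of annual change ratios with
   CVs estimated from the survey anchor years gives 95% envelopes per crop
   group and region.

Every multiplicative correction is audited: the pipeline refuses to finish
unless national sums, anchor-year group amounts, and share/placement sums
conserve to 1e-9 relative.

## Worked example

```python
from nfert import WorldConfig, generate_world, run_pipeline

world = generate_world(WorldConfig(seed=42))   # 4 countries, 24x48 grid, 1961-2020
result = run_pipeline(world)

cube, rates = result.harea_cube, result.rate_cube
years = list(cube.years)
for y in (1961, 1990, 2020):
    yi = years.index(y)
    area = cube.values[:, yi]
    amount = (rates.total[:, yi] * area).sum()
    print(f"{y}: mean N rate = {amount / area.sum():6.1f} kg N/ha over {area.sum()/1e6:.2f} Mha")
print(result.report)
```

prints

```
1961: mean N rate =   33.8 kg N/ha over 1.65 Mha
1990: mean N rate =   63.6 kg N/ha over 4.54 Mha
2020: mean N rate =   86.8 kg N/ha over 6.01 Mha
conservation audits:
  harea_vs_national            max_rel_err=1.873e-15  [ok]
  sn_county_vs_national        max_rel_err=2.736e-16  [ok]
  fubc_anchor_amounts          max_rel_err=2.290e-16  [ok]
  type_share_sum               max_rel_err=4.441e-16  [ok]
  placement_sum                max_rel_err=0.000e+00  [ok]
```

The synthetic planet's area-weighted mean rate rises from 33.8 to
86.8 kg N ha⁻¹ as the generator's adoption curves play out, and every
stage's mass balance closes at machine precision.  On a *noise-free* world
the reconstructed crop-specific rates equal the generator's ground truth to
~1e-15 relative — the constant-ratio algebra is exact when its premise
holds.

The same run from the shell:

```sh
nfert generate --config world.yaml --out world/     # YAML overrides, e.g. seed: 42
nfert run --world world/ --out dataset/             # 21 rate files + harvested area
nfert uncertainty --world world/ --iters 1000 --seed 7 --out envelope.csv
nfert validate --world world/                       # conservation audit report
```

`dataset/` then holds `N_rate_{Crop}_1961-2020.h5` (26 records each,
`{Type}_{Surface|Deep}`, kg N per ha of harvested area) and
`Harvested_area_1961-2020.h5` (21 crop records, ha per cell), written with
WGS84 grid metadata.

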