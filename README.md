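# mastsync

Continental-scale spatial synchrony analysis for mast-eating small mammal
populations — from raw box-trapping records and daily weather to
effort-corrected abundance indices, pairwise Spearman synchrony matrices,
distance-binned spatial correlograms with bootstrap confidence intervals,
and multiple regression on distance matrices (MRM) with permutation
inference.

## The problem

Populations of seed-eating rodents (*Peromyscus*, *Myodes*, woodrats and
relatives) track pulses of tree seed production ("mast seeding").  Because
masting is cued by climate — specifically by the *difference* of two
successive July mean temperatures, ΔT — and because continental climate
modes push summer temperatures in opposite directions at opposite ends of a
continent, rodent dynamics thousands of kilometres apart can fluctuate in
*anti-phase*: an **ecological dipole**.  Detecting one requires

1. an effort-corrected abundance index per site and species
   (unique tagged individuals per trap night per year),
2. pairwise synchrony — Spearman ρ between annual series,
3. a spatial correlogram: median ρ per distance class
   (< 50, 50–500, 500–1000, 1000–2000, 2000–3000, ≥ 3000 km) with a
   percentile bootstrap CI for each median (the class is significant when
   the CI excludes 0; a significantly *negative* far class is the dipole),
4. MRM: regressing the synchrony matrix on site proximity
   (1 − d/d_max) and on the synchrony matrices of five annual climate
   variables — JulyTemp_t, JunePrecip_t, JanuaryTemp_t, JanuaryPrecip_t and
   ΔT₂₋₃ = JulyTemp(t−2) − JulyTemp(t−3) — with p-values from joint
   row/column permutations of the response matrix (four models: space-only,
   direct climate, indirect climate, saturated).

The package ships a synthetic-world generator (`mastsync.simulate`) that
emulates NEON-style trapping (100-trap grids, 3–8 grids per site, bouts of
three nights, COVID-like missing site-years) and Daymet-style daily weather
with a controllable July-temperature dipole, so the whole chain can be
tested against known ground truth without downloading anything.

## Worked example

```python
from mastsync import WorldConfig, simulate_world, analyze_world

world = simulate_world(WorldConfig(seed=42))   # 23 sites, 2013-2022
res = analyze_world(world, seed=0)

print(f"retained series: {len(res['series'])}")
print(res["correlogram"].bins[["lower", "upper", "n_pairs", "median",
                               "ci_lo", "ci_hi", "significant"]]
      .round(3).to_string(index=False))
space = res["fits"]["space"]
print(f"space-only MRM: proximity coefficient "
      f"{space.coefficients['proximity']:.3f}, "
      f"p = {space.coefficient_p['proximity']:.3f}")
```

prints

```
retained series: 44
 lower  upper  n_pairs  median  ci_lo  ci_hi  significant
   0.0   50.0        9   0.867  0.733  0.939         True
  50.0  500.0      123   0.927  0.903  0.929         True
 500.0 1000.0      217   0.903  0.891  0.915         True
1000.0 2000.0      193   0.709  0.143  0.806         True
2000.0 3000.0      235  -0.750 -0.770 -0.733         True
3000.0    inf      142  -0.721 -0.745 -0.709         True
space-only MRM: proximity coefficient 2.490, p = 0.001
```

Synchrony is high and positive among nearby sites, decays with distance,
and is significantly **negative** beyond 2000 km — the generator's built-in
dipole, recovered end-to-end from raw trap-night records.  The positive
proximity coefficient (p = 0.001, from 1000 response permutations) says the
closer two sites are, the more synchronous their rodent dynamics.

## Command line

Each stage is also a CLI subcommand, chained by `all`:

```bash
mastsync simulate --out sim/ --seed 1
mastsync index --records sim/trapping.csv --out idx/
mastsync climate --daily sim/daily_climate.csv --years 2013:2022 --out annual.csv
mastsync all --out run/ --seed 1      # full pipeline + manifest.json
```

The manifest records the config hash, every stage seed, and row counts
in/out of each filter, so series attrition is auditable.

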