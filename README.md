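# luces

**L**and-**U**se **C**hange and **E**cosystem **S**ervices: a tested,
reusable Python implementation of the scenario-simulation chain used to
study how urbanisation-driven land conversion reshapes the monetary value
of ecosystem services in rapidly urbanising regions.

The pipeline has four stages, each usable on its own:

1. **Markov demand** — estimate a 6-class transition matrix
   (cultivated, woodland, grassland, water, built, unused) from two
   land-use snapshots and project per-class cell demand to a horizon
   date; policy scenarios (*natural evolution*, *cultivated-land
   protection*, *ecological protection*) adjust the projection by
   flooring protected classes at their current extent, paid for out of
   built-land growth.
2. **ANN-suitability cellular automata** (FLUS-style) — a
   single-hidden-layer network maps spatial drivers (DEM, slope, aspect,
   GDP, population, accessibility distances) to per-cell class
   suitability probabilities sp(p, k); allocation iterates

   `TProb(p,k) = sp(p,k) · Ω(p,k) · Inertia_k · (1 − sc_{c→k})`

   with Ω the 3×3 Moore-neighborhood share of class k weighted by ω_k,
   Inertia_k an adaptive coefficient driven by successive demand gaps,
   sc the conversion-cost matrix, and roulette-wheel competition under
   constraint masks until class counts meet demand.  Validation uses
   overall accuracy, Cohen's kappa, ROC AUC and the figure of merit.
3. **Equivalent-factor valuation** — an 11-service × 6-class coefficient
   table (units 100 yuan·hm⁻²·yr⁻¹, packaged) prices each landscape via
   `ESV = Σ_k A_k·V_ck`; results aggregate to an analysis grid as
   UESV = ESV/S and are classed into 5 Jenks natural-break levels.
   The regional anchor E = (1/7)·Σ m_i p_i q_i / M is derived from crop
   statistics.
4. **Trade-off / synergy mapping** — Pearson correlation, bivariate
   global and local Moran's I between service-category UESV surfaces on
   queen-contiguity weights, with conditional-permutation significance;
   HH/LL clusters read as synergy, HL/LH as trade-off.

Because the original study's rasters are not deposited, the package
ships a first-class synthetic-landscape generator with planted ground
truth (driver-dependent multinomial class membership, known transition
matrix), so every stage is verified by statistical recovery tests.

## Worked example

```python
from luces import run_scenario

bundle = run_scenario({"seed": 1, "scenario": "natural_evolution"})
print(bundle["metrics"])
print(bundle["demand"].to_series().to_dict())
print(float(bundle["esv"]["total"]))
```

On the default 64×64 synthetic landscape this prints (abridged):

```
{'overall_accuracy': 0.8535, 'kappa': 0.8067, 'figure_of_merit': 0.0132,
 'mean_roc_auc': 0.9125}
{'cultivated': 1202, 'woodland': 524, 'grassland': 1240,
 'water': 421, 'built': 578, 'unused': 131}
120454.89
```

The hindcast validation (allocating the second snapshot from the first)
agrees with the observed map on 85% of cells (kappa 0.81); the trained
network separates the planted classes with mean AUC 0.91; the projected
demand — note the built-land growth at the expense of cultivated and
grassland — is met exactly by the allocation; and the simulated
landscape is worth 120,455 hundred yuan (≈12.0 million yuan) per year
under the packaged coefficient table.  Rerunning with
`scenario="cultivated_protection"` floors cultivated demand at its
current extent and yields a higher total (122,493 hundred yuan),
the damping effect of protection policies.

A command-line interface mirrors the library:

```bash
luces run-all --seed 1 --out runs/        # all three scenarios
luces esv runs/natural_evolution/sim_future.asc --grid-size 240 --out esv/
```

Rasters are exchanged as ESRI ASCII grids (`.asc`), tables as CSV, and
every scenario run writes a `manifest.json` whose artifact hashes are
byte-identical across reruns with the same master seed.

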