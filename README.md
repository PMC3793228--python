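# paramodiv

Net diversification rates of biodiversity-hotspot plant lineages:
method-of-moments estimation from clade richness and crown age,
per-hotspot bootstrap comparison and per-area density metrics,
fastest-lineage Monte-Carlo resampling, Pleistocene divergence counting
on chronograms, and birth–death simulators for validating all of it
with known ground truth.

## The science

Fast, recent plant radiations — the high-Andean Páramo grasslands, the
Hawaiian archipelago, the Cape Floristic Region — are natural
laboratories for speciation.  Given a clade's standing richness *N* and
the age *T* (Ma) of its crown node from a dated molecular phylogeny,
the net diversification rate r = λ − μ (speciation minus extinction,
per lineage per Myr) is estimated by the classical pure-birth form

    r̂ = (ln N − ln N0) / T        (N0 = 2 for a crown group)

and, when a relative extinction fraction ε = μ/λ is assumed, by the
Magallón–Sanderson closed forms that invert the expected richness of a
birth–death clade conditioned on survival (see `docs/methods.md` for
the formulas and their derivation-by-conditioning).

On top of the estimator the package provides:

- **Hotspot comparison** — arithmetic mean of a hotspot's per-lineage
  rates with a 95% percentile-bootstrap CI, plus species/km² and
  speciation events per Myr per km², and a validation report that flags
  published summary cells that cannot be recomputed from their own row.
- **Fastest-lineage resampling** — the probability that the single
  fastest lineage in a stratified draw (5 per hotspot, without
  replacement) comes from each hotspot, with run-length statistics,
  estimated by a seeded two-level Monte Carlo and validated against an
  exact enumeration oracle.
- **Chronogram metrics** — node ages, crown age, ultrametricity checks,
  and the count of tips whose divergence from their parent node falls
  within the Pleistocene (< 2.58 Ma).
- **Simulators** — crown-start Yule and reconstructed birth–death trees
  with recorded event times, and log-normal per-hotspot rate tables.

The 13-lineage Páramo table and the eight-hotspot metadata table ship
with the package (`load_paramo_lineages()`, `load_hotspot_metadata()`).

## Worked example

```python
>>> import paramodiv as pv
>>> records = pv.load_paramo_lineages()
>>> table = pv.rate_table(records)          # crown convention, eps = 0
>>> aragoa = table.set_index("lineage_id").loc["Aragoa"]
>>> round(float(aragoa["r_mean_age"]), 2)   # 17 species, crown age 0.42 Ma
5.1
>>> pv.hotspot_mean_rate(table["r_mean_age"].dropna())
1.3579138550976002
>>> pv.speciation_density(_, 35000) * 1e6   # events/Myr/km2, x10^-6
38.797538717074296
```

A 17-species clade whose crown node is only 0.42 Ma old implies 5.10
net speciation events per lineage per Myr — among the fastest plant
diversification rates measured anywhere.  Averaged over the 13 Páramo
lineages the hotspot runs at 1.36 events/lineage/Myr, which over its
35,000 km² works out to 38.80 × 10⁻⁶ speciation events per Myr per km².

Each script in `examples/` exercises one capability end to end and
prints annotated output:

```sh
python examples/lineage_rates.py
python examples/extinction_corrected_rates.py
python examples/hotspot_comparison.py
python examples/fastest_lineage_resampling.py
python examples/pleistocene_counts.py
python examples/birth_death_recovery.py
```

A thin CLI wraps the same functions for shell use:

```sh
divhotspot rates --lineages lineages.csv --out rates.csv
divhotspot resample --rates rates_by_hotspot.csv --k 5 --seed 42 --out out.json
divhotspot pleistocene --tree chronogram.nwk --threshold 2.58
divhotspot all --lineages lineages.csv --hotspots hotspots.csv --out results/
```

## Layout

- `src/paramodiv/` — `rates` (estimators), `hotspots` (means, bootstrap,
  densities), `resampling` (Monte Carlo + exact oracle), `trees`
  (chronogram metrics), `simulate` (generators), `io`/`datasets`
  (CSV schemas, packaged tables), `pipeline` + `cli` (orchestration).
- `docs/methods.md` — model, assumptions, numerical choices, limitations.
- `tests/` — unit, property and acceptance tests (`pytest`).
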