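# foramdiv

Phanerozoic-scale analysis of benthic foraminiferal **wall-type diversity and
turnover** from a genus-level range chart. Foraminifera build their tests
(shells) by precipitating CaCO₃ (*calcareous*, including porcelaneous and
aragonitic walls), by cementing sediment grains (*agglutinated*), or from
organic material (*organic*) — so a range chart labelled by wall type records
how marine calcifiers and non-calcifiers fared through 541 Myr of changing
ocean chemistry, including the Big Five mass extinctions.

The package is aimed at paleobiologists working with interval-valued
(first/last appearance) taxon data. From a genus table with habit, wall type
and origination/extinction epochs it computes:

- **per-epoch diversity and proportional diversity** by wall type, with the
  four-way occurrence classification (singleton / originator /
  extinct-in-bin / boundary crosser) and a singleton-removal sensitivity
  check for the pull of the recent;
- **per-capita origination and extinction rates** from boundary crossers.
  With N_bt the genera crossing both boundaries of a bin, N_t those crossing
  its top and N_b those crossing its bottom, and Δt the bin length in Myr:

      p̂ = −ln(N_bt / N_t) / Δt        q̂ = −ln(N_bt / N_b) / Δt

  Singletons are invisible to these estimators; undefined bins are flagged,
  not zeroed. Extant genera count as crossing the Holocene top, so the
  terminal bin reflects only true extinctions;
- **bootstrap null envelopes**: the expected rate range for a random,
  size-matched group of benthic genera (default 1000 replicates, 95% CI),
  against which each wall type's observed rates are flagged
  below/within/above;
- **era-split trend fits**: a GLM with square-root link and Gamma variance,
  sqrt(μ) = β0 + β1·age, fitted separately to the Palaeozoic and the
  Mesozoic+Cenozoic, with Wald slope tests on Pearson dispersion and ±1 SE
  prediction bands;
- **synthetic datasets** from a genus-level birth–death process with
  per-wall-type rates and instantaneous kill pulses, with exact times kept as
  truth, so every stage above is testable against known parameters.

Everything is binned on an embedded epoch-level ICS (2013) timescale
(541–0 Ma, 38 bins) with stage→epoch alias resolution, and all I/O is plain
CSV. See `docs/methods.md` for the full model description and conventions.

## Worked example

The `analysis/` drivers run the whole study on a simulated reference dataset
(a ~2500-genus benthic clade with a calcareous-selective end-Permian pulse
and an agglutinated-leaning end-Cretaceous pulse):

```sh
python analysis/01_simulate_dataset.py   # writes results/synthetic_genera.csv
python analysis/02_diversity.py
python analysis/03_rates.py
python analysis/04_null_envelopes.py
python analysis/05_glm_trends.py
```

With the default seed this prints, among other lines:

```
simulated 2528 genera (seed=1): {'calcareous': 1352, 'agglutinated': 1103, 'organic': 73}
calcareous proportion across the end-Permian pulse: 56% (Lopingian) -> 28% (Early Triassic)
Lopingian extinction rate: calcareous 0.2395/Myr vs agglutinated 0.0666/Myr
  -> calcareous extinction 3.6x the agglutinated rate at the pulse
calcareous (n=1352): extinction above the null in [... 'Lopingian', ...]
agglutinated (n=1103): extinction above the null in no epochs
Mesozoic+Cenozoic  calcareous origination     slope +2.76e-04/Ma (p=0.002 *, n=14, excluded=1)
```

Reading this: the planted end-Permian pulse halves the calcareous share of
diversity and produces a Lopingian calcareous extinction rate several times
the agglutinated one; the size-matched bootstrap null flags calcareous
turnover as above-expected there (calcareous genera really do turn over
faster than a random draw of all benthic genera in this dataset), while
agglutinated rates stay within expectation; and the era-split Gamma GLM
recovers a significant positive slope (rates higher deeper in time) for
Mesozoic+Cenozoic calcareous originations. Each script also writes tidy CSV
tables under `results/`.

The same pipeline runs on real data from a CSV with columns
`genus, habit, wall_type_original, fad_interval, lad_interval` (free-text
interval names; arbitrary headers adaptable via a column map):

```sh
foramdiv validate --input my_genera.csv
foramdiv all --input my_genera.csv --outdir out/ --seed 1 --n-reps 1000
```

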