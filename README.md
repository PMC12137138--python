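# riverc14

Radiocarbon source apportionment of river CO₂ emissions.

Rivers and streams emit roughly 2 Pg C yr⁻¹ of CO₂ to the atmosphere. The
radiocarbon content of river dissolved inorganic carbon (DIC), CO₂ and CH₄
— reported as fraction modern, F¹⁴C — tells us how old that carbon is:
values above 1 carry bomb-test carbon fixed since 1955, values below 1
indicate contributions from aged soil organic matter and from
radiocarbon-dead ("petrogenic") rock carbon mobilized by weathering.
`riverc14` provides the toolchain for working with such measurements at
the global scale, for biogeochemists and carbon-cycle modellers:

* **Unit conversions** between F¹⁴C, Δ¹⁴C and conventional ¹⁴C age
  (`riverc14.isotope`), using the true decay constant λ = 1/8267 yr⁻¹ for
  Δ¹⁴C and the Libby mean life of 8033 yr for conventional ages.
* **Atmospheric normalization** (`riverc14.atmosphere`): manage the annual
  atmospheric ¹⁴CO₂ record, extend it past its last measured year on the
  2014–2019 linear trend, and compute F¹⁴C_atm = Fm_sample / Fm_atmosphere.
* **Database harmonization** (`riverc14.database`): validated CSV ingest,
  averaging of locations repeat-sampled more than four times in a calendar
  year, catchment-size / lithology / biome classifications, grouped
  summaries and paired DIC–CO₂ offsets.
* **Source apportionment** of the global river CO₂ flux into decadal,
  millennial and petrogenic carbon via two independent routes:
  a petrogenic-constrained Monte Carlo mass balance
  (`riverc14.mixing.MonteCarloSourceApportionment`) and a Bayesian
  three-endmember mixing model with no flux prior
  (`riverc14.bayes.BayesianSourceApportionment`). Both are scikit-learn
  style estimators (`fit`, `predict`, `get_params`).
* **Synthetic data** (`riverc14.simulate`): a parametric bomb-curve record
  and a generative observation model with recorded ground truth, so the
  whole pipeline is testable end to end without any external download.

## The model

The global river DIC flux is a mass balance (Pg C yr⁻¹):

```
total DIC flux = lateral DIC export + vertical CO2 emission + carbonate precipitation
               = 0.52 ± 0.17      + 2.0 ± 0.2             + 0            ≈ 2.5
```

and its radiocarbon signature is a three-source mixture with a + b + c = 1:

```
F14C_river = a·F14C_decadal + b·F14C_millennial + c·F14C_petro ,   F14C_petro = 0
```

Independent weathering estimates bound the petrogenic input at
0.150–0.218 Pg C yr⁻¹, giving c directly and leaving a non-petrogenic
residual `F14C_river · total / (total − petro)` to be split between the
decadal endmember (atmospheric CO₂ 1950–2023, F¹⁴C = 1.226 ± 0.216) and
the millennial endmember (global 0–30 cm mineral soil, F¹⁴C =
0.841 ± 0.033). A 10,000-run Monte Carlo over the three stated ranges
propagates the uncertainty; proportions are rescaled by (1 − c) and
multiplied by the 2.0 Pg C yr⁻¹ vertical emission flux.

## Worked example

```python
>>> from riverc14 import monte_carlo_partition, partition_to_fluxes
>>> res = monte_carlo_partition(f14c_river=0.919, n_runs=10_000, seed=20250604)
>>> {k: (round(m, 2), round(s, 2)) for k, (m, s) in res.summary.items()}
{'decadal': (0.41, 0.15), 'millennial': (0.52, 0.16),
 'petrogenic': (0.07, 0.01), 'old': (0.59, 0.15)}
>>> {k: round(m, 1) for k, (m, s) in partition_to_fluxes(res).items()}
{'decadal': 0.8, 'millennial': 1.0, 'petrogenic': 0.1, 'old': 1.2}
```

Reading: of the CO₂ emitted by global rivers, 41 ± 15 % comes from carbon
fixed within recent decades, 52 ± 16 % from millennial-aged soil carbon and
7 ± 1 % from rock-derived carbon — so ~59 % ("old" = millennial +
petrogenic, about 1.2 Pg C yr⁻¹) predates the bomb era. The same numbers
are available from the shell:

```
riverc14 mix --f14c-river 0.919 --n-runs 10000 --seed 20250604
riverc14 bayes --f14c-river 0.919 --sigma 0.03 --seed 0
riverc14 simulate --n 1000 --seed 0 --out-observations obs.csv
riverc14 summarize obs.csv --group-by lithology
```

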