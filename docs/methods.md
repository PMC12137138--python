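# Methods

This note documents the models implemented in `riverc14`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Radiocarbon arithmetic

Fraction modern (F¹⁴C) is the primary unit. Δ¹⁴C applies the decay
correction between the collection year *y* and 1950 with the true decay
constant λ = 1/8267 yr⁻¹:

    Δ¹⁴C = 1000 · (F¹⁴C · e^{−λ(y−1950)} − 1)

Conventional ¹⁴C ages use the Libby mean life of 8033 yr,
age = −8033 · ln F¹⁴C, by radiocarbon convention. The two constants are
deliberately different; a regression test pins the conventional-age
constant by checking that 8033 (and not 8267) reproduces the reference
F¹⁴C/age pairs (0.914 → 722, 0.961 → 320, 0.879 → 1036, and the
1.0-vs-0.98 offset of 162 yr) to the nearest year. Samples with F¹⁴C > 1
have no conventional age and are reported through a "modern" sentinel,
never as negative ages. Uncertainties on derived ages use first-order
propagation, σ_age = 8033 · σ_F / F.

## Atmospheric record

Normalization divides a sample's F¹⁴C by the annual atmospheric ¹⁴CO₂
F¹⁴C of its collection year. Records finer than annual are averaged to
annual means first, and a single global curve is used (no hemisphere
split): the normalization targets the collection year, not the collection
site. Extension beyond the last measured year fits an ordinary
least-squares line to the six annual values 2014–2019 — the flattening
tail of the bomb curve — and evaluates it forward; extrapolated years are
tagged as such in the record and in every normalized value. "Linear OLS on
the six annual means" is the minimal reading of "extrapolating the
declining annual trend"; the fit basis is recorded in output metadata.
Out-of-record years raise; values are never clamped.

## Database harmonization

Rows are validated against the schema (compound ∈ {DIC, CO₂, CH₄}, year ≥
1950, coordinate/flag/area ranges); failures are dropped with logged
reasons and the metadata keeps the conservation identity
kept + collapsed-away + dropped = input. F¹⁴C and Δ¹⁴C back-fill each
other; conventional ages are always recomputed.

Repeat collapsing averages any (site, calendar-year, compound) group with
more than four measurements into one record. The grouping is per compound,
since compounds are analysed separately throughout. The averaged record's
uncertainty is the larger of (i) the standard error of the replicate F¹⁴C
values and (ii) the root-mean-square of the replicate analytical σs — a
conservative stand-in, since the upstream averaging convention for such
repeats is a lab-practice citation without printed formulas.

Catchment sizes classify as small (≤ 10 km², the HydroATLAS basin
resolution limit) or large, and into left-open decade bins labelled by
their upper bound (0–10, 100, …, 1,000,000 for > 100,000 km²). Lithology
codes map to sedimentary / igneous / metamorphic, with no-data and
ice-covered reaches excluded from lithology groupings only; biome codes
map to eight classes (polar desert folds into deserts). Unknown codes warn
and fall into the excluded/unclassified bucket rather than failing.

## Monte Carlo mass balance

The global constants: lateral DIC export 0.52 ± 0.17, vertical CO₂
emission 2.0 ± 0.2, carbonate precipitation 0 (negligible globally),
petrogenic weathering input 0.150–0.218 Pg C yr⁻¹. The total flux's
quadrature uncertainty is √(0.17² + 0.2²) ≈ 0.26 ≈ 0.3; some published
statements of this total carry ±0.4, which quadrature does not reproduce —
we report the quadrature value.

Each of the 10,000 runs draws the petrogenic flux and the decadal and
millennial endmember F¹⁴C values independently and **uniformly** over
their stated ranges (each range is mean ± 1σ of the underlying estimate).
Uniform is the minimal reading of "varying … over the range"; it
reproduces the reference means and σs of the partition, and a
truncated-normal alternative sits behind `distribution="truncnorm"`. The
petrogenic proportion is c = draw / total with the total held fixed at its
mean (an option draws the total too, off by default). Raw two-endmember
proportions are not clamped: out-of-[0, 1] values would be flagged, but
with the default non-overlapping ranges they cannot occur. Final
proportions a = a_raw(1 − c), b = (1 − a_raw)(1 − c) sum to one with c
exactly, per run. Per-source emission fluxes multiply per-run proportions
by a Normal(2.0, 0.2) draw of the vertical emission; summaries are means
± 1σ over runs. The default seed is 20250604 and every stochastic output
carries its seed.

The soil-carbon residence-time bracket divides the soil stock by the
millennial loss flux at opposite uncertainty extremes:
(840 − 280)/(1.1 + 0.3) ≈ 400 yr to (840 + 280)/(1.1 − 0.3) = 1400 yr.

The default F¹⁴C_river is 0.919 (the database-wide mean signature); the
estimator recomputes it as the mean of whatever observations `fit`
receives.

## Bayesian mixing model

The cross-check drops the flux prior entirely: proportions (a, b, c) get a
flat Dirichlet prior on the simplex, the decadal and millennial endmembers
truncated-normal priors on their stated ranges, the petrogenic endmember
is fixed at F¹⁴C = 0, and the observed mean F¹⁴C_river enters a Gaussian
likelihood (σ defaults to 0.03, the order of the millennial endmember σ,
or to the standard error of the supplied observations). This is the
minimal standard mixing model; all choices are estimator parameters.

The sampler is random-walk Metropolis on the softmax parametrization with
the log-Jacobian term (Σ log pᵢ) that makes the flat Dirichlet exact, run
as 4 independent chains with per-chain step-size adaptation toward ~30 %
acceptance during warm-up. Defaults (20,000 post-warm-up iterations,
5,000 warm-up) were set by benchmarking posterior-mean error against a
4-million-draw importance-sampling oracle of the same posterior
(≤ 0.011 per source across seeds); the oracle's moments are frozen into
the test suite as the sampler's reference. Convergence is a contract, not
a hope: the fit raises if rank-normalized R-hat (arviz) exceeds 1.05 for
any parameter. With the likelihood disabled the sampler reproduces the
Dirichlet(1,1,1) prior moments, which is tested.

For the default configuration the posterior concentrates along the ridge
a·F_dec + b·F_mil ≈ 0.919, giving means near (0.48, 0.40, 0.12) — in
agreement (well within ±0.15 per source) with the Monte Carlo partition
(0.41, 0.52, 0.07), while attributing somewhat more mass to the petrogenic
source, which here is constrained only by the observation rather than by
the weathering-flux prior.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not any particular real database. Defaults: collection years 1991–2023;
compound mix 85 % DIC / 10 % CO₂ / 5 % CH₄; per-observation proportions
Dirichlet with mean (0.43, 0.50, 0.07) and concentration 20; decadal
carbon sampled from the bomb curve at (year − lag) with lag ~ N(10, 3²)
truncated at 0; millennial age lognormal with median 1500 yr (σ_log 0.5),
converted to F¹⁴C with the true decay constant; measurement noise
N(0, 0.02) truncated so F¹⁴C stays positive; 5 % of sites repeat-sampled
six times in a year to exercise the collapsing rule. The bomb curve itself
is parametric (plateau 0.975, logistic rise to 1.85 in 1964, e-folding
decay of 16 yr toward 1.0) — an emulation, not the published compilation;
every analysis that cites printed global constants is independent of it.
`concentration=inf` and zero components of the Dirichlet mean produce
exact degenerate mixtures for boundary tests. Optional per-lithology
offsets can impose the observed sedimentary < igneous < metamorphic
ordering; they are off by default and documented as emulation.

The recovery experiment closes the loop: simulate → write CSV → ingest →
collapse → mean F¹⁴C_river → Monte Carlo partition with endmembers matched
to the generator's brute-force expectations and the petrogenic range
pinned at c_true · total. At 1,000 observations and 20 replicates the
per-source bias stays below 0.05. Because the matched-endmember inversion
is algebraically unbiased, this demonstrates the pipeline's bookkeeping
(ingest, collapsing, averaging, rescaling), not robustness to endmember
misspecification — which no synthetic test can establish for real data.
Problem sizes in the test suite (10,000 Monte Carlo runs, 20 × 1,000
recovery observations, 4 × 20,000 Metropolis iterations) match the scale
of the analysis itself, so the full suite runs in well under a minute.

## Known limitations

* The generator has no spatial autocorrelation, seasonality, or per-study
  reporting structure; group contrasts it produces are synthetic.
* The Bayesian "model scenarios" averaging used in the original
  cross-check is not public; our single-model posterior is the minimal
  counterpart, and its petrogenic share is prior-sensitive.
* Hemisphere-specific atmospheric curves, IntCal calendar calibration and
  δ¹³C fractionation corrections are out of scope (assumed applied by the
  reporting laboratories).
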