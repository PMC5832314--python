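# omtrace

Source fingerprinting of sediment-associated organic matter, with Monte
Carlo uncertainty analysis, and sediment oxygen demand (SOD) computation
from incubation time series.

## The problem

Fine sediment ingressing river substrates carries organic matter (OM) that
consumes dissolved oxygen as it decays, degrading spawning-gravel habitat
for lithophilous fish. Catchment managers need to know *where the OM comes
from*: farmyard manures and slurries, damaged road verges, decaying
instream vegetation, or human septic waste. Fingerprinting answers this by
matching measurable tracer properties of channel-bed sediment — stable
isotope ratios (δ¹³C, δ¹⁵N), elemental contents (%TOC, %TN) and
near-infrared constituent band intensities — against the same properties
measured in composite samples of each candidate source.

`omtrace` implements the full numerical workflow for analysts running such
reconnaissance surveys, together with a synthetic-data generator with known
ground truth so that every stage is testable without field data.

## The method

1. **Bracket (mass-conservation) test** — a tracer is retained only when
   the sediment range lies inside the envelope spanned by all source
   samples, a necessary condition for linear mixing.
2. **Composite signature selection** — three routes build tracer subsets
   that jointly discriminate the four source categories:
   genetic-algorithm-driven discriminant function analysis (GA-DFA,
   minimising Wilks' Λ subject to stepwise-entry *F*-tests, three top
   signatures), Kruskal–Wallis *H* ranking, and PCA loading ranking. Each
   tracer *i* gets a discriminatory weighting
   *W<sub>i</sub>* = %<sub>i</sub> / %<sub>min</sub> (weakest tracer = 1.00).
3. **Weighted mass-balance unmixing** — source proportions *P* on the
   simplex minimise

   &nbsp;&nbsp;&nbsp;&nbsp;Σ<sub>i</sub> W<sub>i</sub> · SV̄<sub>i</sub>(P) ·
   ((C<sub>i</sub> − Σ<sub>s</sub> P<sub>s</sub> S<sub>si</sub>) / C<sub>i</sub>)²

   where C<sub>i</sub>, S<sub>si</sub> are sediment and source medians and
   SV<sub>si</sub> the inverse within-source coefficient of variation.
   Goodness of fit is GOF = 1 − mean<sub>i</sub>|C<sub>i</sub> − Ĉ<sub>i</sub>|/|C<sub>i</sub>|.
4. **Monte Carlo uncertainty** — medians are perturbed by
   Normal(median, Q<sub>n</sub>) deviates (Q<sub>n</sub> is the
   Rousseeuw–Croux robust scale), truncated to the observed range, with
   Latin hypercube stratification; solutions with GOF > 0.85 are collected
   (default 5,000) and binned into posterior relative frequencies. The
   frequency-weighted average median contribution is
   R = Σ<sub>i</sub> v<sub>i</sub> F<sub>i</sub>.
5. **Combination and summaries** — per-signature R values are combined
   with weights α = mean GOF × overall classification %, and subcatchment
   results averaged to a catchment summary.
6. **SOD** — interval consumption rates SOC = (m₁ − m₂)/t from headspace O₂
   mass, blank-corrected, Q10-normalised to 20 °C (rate × 1.065^(20−T),
   valid for T ≥ 10 °C), integrated over 0–5 and 0–20 days and divided by
   dry sediment mass to give SOD₅ and SOD₂₀ in mg O₂ g⁻¹.

## Worked example

```bash
omtrace simulate --out run --seed 5 --true-p 0.4,0.3,0.2,0.1 --sod-target 5.0
omtrace unmix --table run/tracer_table.csv --out run --seed 5 --n-accept 40 --n-repeats 1
omtrace sod --table run/oxygen_table.csv --out run
```

prints

```
synthetic: farmyard_manure=0.43, road_verge=0.30, instream_vegetation=0.18, septic_waste=0.10
synthetic-1: SOD5=2.776 SOD20=5.000 mg O2/g
```

The simulated sediment was mixed with true proportions 0.40 / 0.30 / 0.20 /
0.10; the combined frequency-weighted estimates recover them to within a
few percent, and the incubation generated for a 5.0 mg O₂ g⁻¹ SOD₂₀ target
is recovered exactly (SOD₅ is smaller because consumption is incomplete at
day 5). Output CSVs in `run/` hold the per-stage detail: bracket-test
report, signature tables (tracer, %, TDW), per-signature posterior
histograms, combined proportions and the catchment summary, each with the
seed and config hash in its header.

The same steps are available as library calls (`bracket_test`,
`select_ga_dfa` / `select_kw_h` / `select_pca`, `solve`,
`run_monte_carlo`, `combine_signatures`, `compute_sod`, …); the CLI is a
thin layer over `omtrace.pipeline`.

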