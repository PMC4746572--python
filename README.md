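# precisionif

Continuous, tile-based quantification of membrane-marker expression from
dual-channel immunofluorescence of tissue sections — with HER2 in breast
carcinoma as the driving application — plus the Langmuir binding-kinetics
model that explains why short, microfluidically controlled antibody
incubations give a signal proportional to antigen density.

Routine HER2 assessment is semi-quantitative (IHC 0/1+/2+/3+) and equivocal
cases are resolved with expensive FISH copy-number counting. This package
implements the computational half of a quantitative-IF alternative: a slide
is stained for the target (HER2), an epithelial reference (pan-cytokeratin,
CK) and nuclei (DAPI), scanned as a tile mosaic, and scored on a continuous
scale that tracks the *HER2* gene copy number N_FISH. It is aimed at
quantitative-pathology method developers: every stage is a library function,
a synthetic-slide generator replaces patient data, and a small CLI ties the
stages into reproducible runs.

## Model

Per tile, the region of interest is the CK-positive (epithelial) area minus
the dilated DAPI-positive (nuclear) area — Otsu auto-thresholding per channel
— yielding one mean CK and one mean HER2 signal per tile. Per case, tiles
with little epithelium (CK below a case-specific lower threshold) and the 5%
brightest-CK tiles (saturating artifacts) are removed. The retained tiles'
HER2/CK ratios form a frequency histogram fitted with a Gaussian
a·exp(−(x−μ)²/2σ²); with the batch's IHC-3+ positive control as reference,

    M = μ_case / μ_pos      Σ = σ_case / σ_pos      MTP = M · Σ.

The ratio cancels case-level staining-quality variation (it multiplies both
channels), and Σ captures the wider tile-to-tile dispersion of amplified
tumors. Cohort-level, the scores are correlated with N_FISH by Pearson's ρ
and a power-law fit y ~ x^α. The kinetics module provides the Langmuir
closed forms — θ_eq = c_bulk/(c_bulk + K_D), τ = 1/(k_on c_bulk + k_off),
t_d = 1/k_off, θ(t) = θ_eq(1 − e^(−t/τ)) — and spotting-series simulations
of antibody-vs-antigen linearity. See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

Score a small synthetic cohort (2 batches of 5 slides, each batch carrying
one positive and one negative control) entirely in memory:

```python
import precisionif as pf

spec = pf.SyntheticCohortSpec(n_cases=10, batch_size=5, tiles_per_case=60, seed=1)
cohort = pf.generate_cohort(spec)
records = [rec for _, rec in cohort]
measurements = {rec.case_id: pf.measure_case(pf.generate_case(ph))
                for ph, rec in cohort}
results = pf.score_cohort(measurements, records)
print(pf.results_to_frame(results).round(3).to_string(index=False))
```

```text
case_id        role  n_tiles_retained    mu  sigma  m_score  sigma_score  mtp_score qc_status
 case01 pos_control                37 0.957  0.122    1.000        1.000      1.000      pass
 case02 neg_control                38 0.091  0.000    0.095        0.002      0.000      pass
 case03        case                32 1.089  0.101    1.138        0.832      0.947      pass
 case04        case                33 0.170  0.005    0.178        0.041      0.007      pass
 case05        case                39 0.766  0.043    0.800        0.354      0.283      pass
 ...
```

`mu` is the fitted mean HER2/CK ratio; the positive control scores (1, 1, 1)
by construction; the negative control sits near zero on every scale; and the
cases order by their ground-truth expression (case04 barely expresses,
case03 matches the control). The kinetics side:

```python
d = pf.derive(pf.KineticParams())   # typical IgG constants
# tau=90.9 s  t_d=1000 s  K_D=1.0e-09 M  theta_eq=0.909
```

Recognition (τ ≈ 91 s) is an order of magnitude faster than desorption
(t_d = 1000 s), which is why a 2-minute incubation suffices — and a
simulated 2-minute spotting series with 2% signal noise gives an
antibody-vs-antigen Pearson coefficient of 0.9999.

The same workflow runs from the shell on file outputs (per-channel tile
TIFFs + cohort CSV):

```sh
precisionif simulate --out run/ --seed 1
precisionif score --images run/ --cohort run/cohort.csv --out run/results/
precisionif correlate --scores run/results/scores.csv --cohort run/cohort.csv \
    --out run/correlations.csv
precisionif kinetics --t-incubation 120
```

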