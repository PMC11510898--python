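# salgae

Salinity-response modelling and compound-productivity analysis for marine
microalgal batch cultures.

Marine microalgae — haptophytes, dinoflagellates, raphidophytes — are grown
at industrial scale for carotenoids (fucoxanthin, peridinin), long-chain
polyunsaturated fatty acids (EPA, DHA) and bioactive metabolites. Culture-medium
salinity is one of the cheapest process levers: it shifts biomass productivity,
pigment de-epoxidation state, fatty-acid saturation and haemolytic activity.
`salgae` implements the computational chain of a salinity-screening experiment,
from raw optical-density readings to a fitted salinity optimum and derived
composition indices, for process engineers and phycologists designing
single-stage (S1) or two-stage salt-shock (S2) cultivations.

## The model

Endpoint biomass productivity over a culture window is

    Pb = (Cb_f − Cb_i) / (t_f − t_i)        [mg·L⁻¹·day⁻¹]

and its response to salinity S (PSU) is modelled by a Gaussian-type tolerance
curve

    Pb(S) = Pmax + a · (exp(−((S − Sopt)/b)²) − 1)

where `Pmax` is the productivity at the optimum salinity `Sopt`, `b` is the
response width and `a` the suppression depth far from the optimum (the
far-field limit `Pmax − a` may be negative: growth inhibition). For
halotolerant organisms that respond weakly over wide salinity ranges, the
same curve is fitted on `log10(S)`. Fits are validated with the
predictive-microbiology statistics

    RMSE = sqrt(Σ(Pb_p − Pb_e)²/n)
    Bf   = 10^(Σ log10(Pb_p/Pb_e)/n)      (bias factor)
    Af   = 10^(Σ |log10(Pb_p/Pb_e)|/n)    (accuracy factor)

plus the coefficient of determination r². Downstream modules compute compound
productivities `Pp = Pb·X` (X = mass fraction of dry weight), xanthophyll
de-epoxidation states DES = 100·Dtx/(Dtx+Ddx) and
DES = 100·(0.5·Ax+Zx)/(Vx+Ax+Zx), SFA/MUFA/PUFA class aggregates, and the
equivalent saponin potential ESP = EC50(saponin)/EC50(extract) for haemolytic
activity. A synthetic-data generator produces lag/exponential/stationary
growth curves whose noiseless endpoint productivity equals the true response
model exactly, so the whole pipeline is testable end to end.

## Worked example

Simulate a ten-salinity screen (5–50 PSU, 5% measurement noise), compute
endpoint productivities and fit the response model:

```
$ salgae simulate --out demo/sim --seed 7 --noise-sigma 0.05
wrote demo/sim/cultures.csv (10 series)
$ salgae productivity --input demo/sim/cultures.csv --out demo/prod
wrote demo/prod/productivity.csv (10 rows)
$ salgae fit --input demo/prod/productivity.csv --out demo/fit
wrote demo/fit/fitted_models.csv (1 model(s))
$ salgae report --input demo/fit/fitted_models.csv --out demo/report
  species stage     rmse       af       bf       r2
synthetic    S1 0.511862 1.041519 1.001407 0.977586
```

The generating model had Pmax = 15 mg·L⁻¹·day⁻¹ at Sopt = 30 PSU (a = 10,
b = 15); from the noisy screen the fit recovers

```
pmax 15.66  a 9.79  b 12.42  sopt_psu 29.14
```

i.e. the optimum within ~1 PSU and the maximum productivity within ~5%.
Bf ≈ 1.0 means no systematic bias; Af ≈ 1.04 means predictions deviate from
observations by ~4% on average; both close to 1 indicate the model is
adequate for process design. With `--noise-sigma 0` the four parameters are
recovered to machine precision — the fitting error is then exactly zero by
construction of the generator.

The same library surface is importable directly
(`from salgae import fit, predict, SalinityObservation, ...`); see
`docs/methods.md` for the model assumptions and numerical choices.

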