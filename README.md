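# rnacleave

Kinetic analysis of RNA phosphodiester cleavage catalyzed by a
water-soluble arylmercury complex, studied with the dinucleoside
monophosphate model compound adenylyl-3′,5′-(2′,3′-*O*-methyleneadenosine)
(the "3′,5′ dimer") and its 2′,5′ isomer. The package is for
physical-organic chemists who fit pH–rate profiles and
catalyst-concentration series of nucleic-acid model reactions: it
evaluates and fits the rate law, simulates the full reaction network, and
generates realistic synthetic HPLC-style data so every stage of the
analysis can be exercised and validated without laboratory measurements.

## The model

The observed first-order rate constant for cleavage of the isomeric dimer
pool is the four-term law

```
k_cl = kH·[H⁺] + kH2O + kcat·[1-Hg] · Ka1·Ka2/([H⁺]² + Ka1·[H⁺] + Ka1·Ka2)
       + kOH·KW/[H⁺]
```

with hydronium-, water-, catalyst- and hydroxide-dependent contributions.
`[1-Hg]` is the arylmercury catalyst concentration, `KW = 6.2×10⁻¹³ M²` is
the ionic product of water at the working conditions (90 °C, *I* = 0.1 M),
and the two kinetic acid-dissociation constants are constrained equal
(`Ka1 = Ka2 = Ka`): the catalyzed reaction shows an apparent second-order
dependence on [OH⁻] between pH 5 and 6, which makes only their common
value identifiable. The catalyzed reaction network is

```
N4 ⇌ N5           isomerization (phosphate migration)
N4, N5 → N6 + 2′,3′-cAMP     transesterification cleavage
2′,3′-cAMP → 2′/3′-AMP → adenosine   consecutive hydrolysis
```

an all-first-order system solved exactly by the matrix exponential.
Parameters are estimated by nonlinear least squares on log₁₀(k_obs) with
all constants log-parameterized (hence positive), and the slope of a
weighted linear fit of k_obs versus catalyst concentration gives the
apparent second-order catalytic constant at fixed pH.

## Worked example

```python
import numpy as np
from rnacleave import (
    TABLE1_BACKGROUND, TABLE1_CATALYST, Conditions,
    acceleration_ratio, eq1_rate, ExperimentDesign, NoiseModel,
    gen_ph_profile, gen_conc_series, fit_ph_profile, fit_conc_series,
    profile_report,
)

# background cleavage rate at pH 7 and the 1 mM catalytic acceleration
print(f"{eq1_rate(TABLE1_BACKGROUND, Conditions(pH=7.0)):.3e}")   # 7.502e-07
cond = Conditions(pH=7.0, cat_conc=1e-3)
print(f"{acceleration_ratio(TABLE1_BACKGROUND, TABLE1_CATALYST, cond):.2f}")
# 2.77  -> roughly the reported three-fold acceleration at 1 mM

# recover the constants from a noise-free synthetic profile
prof = gen_ph_profile(TABLE1_CATALYST, ExperimentDesign(ph_step=0.25),
                      cat_conc=1e-3)
fit = fit_ph_profile(prof)
print(profile_report(fit, prof)["text"])
```

```
parameter            value      +/-        units
kH                    3    1.5e-15   10^-3 M^-1 s^-1
kH2O                  1    1.3e-15   10^-7 s^-1
kOH                0.07      4e-17   M^-1 s^-1
kcat                1.6    7.9e-16   10^-3 M^-1 s^-1
Ka                    3    2.6e-15   10^-6 M
```

The noise-free fit returns the generating constants exactly (standard
errors at machine precision). A noisy catalyst series behaves like the
real concentration-dependence experiment:

```python
rng = np.random.default_rng(1)
series = gen_conc_series(TABLE1_CATALYST, ExperimentDesign(), 7.0,
                         NoiseModel(cv=0.1), rng)
fc = fit_conc_series(series)
print(f"{fc.estimates['slope']:.2e} +/- {fc.standard_errors['slope']:.1e}")
# 1.54e-03 +/- 5.6e-05  (M^-1 s^-1): the apparent catalytic constant,
# i.e. kcat times the speciation fraction 0.967 at pH 7
```

A command-line pipeline wraps the same functions:

```
rnacleave simulate --seed 1 --outdir out/
rnacleave fit-profile --config fit.json
rnacleave fit-conc --input out/conc_series.csv --outdir out/
```

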