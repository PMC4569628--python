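# phycofit

Kinetic modelling of microalgal batch cultures: logistic growth and
Luedeking–Piret lipid production, with scikit-learn-style parameter
estimation, fit diagnostics, Gaden product-class assignment, a
synthetic-data generator, and a small CLI.

The package is aimed at bioprocess and algal-biofuel researchers who
have (time, biomass, lipid) series from batch photobioreactor runs —
for example *Chlorella salina* or *Nannochloropsis oculata* grown under
nitrogen-replete (N⁺) or nitrogen-deplete (N⁻) conditions — and want
the standard two-step kinetic analysis: estimate the growth constants,
then the product-formation constants, and classify how tightly lipid
production is coupled to growth.

## The model

Biomass follows the logistic law

    dx/dt = k·x·(1 − x/xs),     x(0) = x0

with closed form

    x(t) = x0·e^{kt} / (1 − (x0/xs)·(1 − e^{kt}))

where `k` (h⁻¹) is the rate constant and `xs` (g/L) the stationary-phase
biomass (carrying capacity). Lipid production follows the
Luedeking–Piret law

    dp/dt = α·dx/dt + β·x

with a growth-associated coefficient `α` (g lipid / g biomass) and a
non-growth-associated coefficient `β` (g lipid / g biomass / h). Along
the logistic trajectory this integrates exactly to

    P(t) = p0 + α·(x(t) − x0) + β·(xs/k)·ln[1 − (x0/xs)·(1 − e^{kt})]

which is *linear* in (α, β) once the growth parameters are known — so
the product fit is a plain least-squares step. The fitted (α, β) decide
the Gaden class: I (β = 0, fully growth-associated), II (both nonzero,
partially associated), III (α = 0, non-growth-associated).

## Worked example

```python
from phycofit import preset, generate_dataset, fit_condition

cfg = preset("C. salina N+", noise_sd_biomass=0.02,
             noise_sd_product=0.005, seed=7)
data = generate_dataset(cfg)        # 30 samples over 20 h, noisy
res = fit_condition(data)

print(f"condition      : {res.condition_label}")
print(f"k    (h^-1)    : {res.growth.k:.4f}   (generating value 0.4441)")
print(f"x0, xs (g/L)   : {res.growth.x0:.4f}, {res.growth.xs:.4f}")
print(f"alpha          : {res.prod.alpha:.4f}   (generating value 0.125)")
print(f"beta (h^-1)    : {res.prod.beta:.5f}  (generating value 0.002)")
print(f"R^2 growth     : {res.r2_growth:.4f}")
print(f"% error growth : {res.pct_error_growth:.2f}")
print(f"Gaden class    : {res.gaden_class}")
```

prints

```
condition      : C. salina N+
k    (h^-1)    : 0.4406   (generating value 0.4441)
x0, xs (g/L)   : 0.0513, 1.9960
alpha          : 0.1151   (generating value 0.125)
beta (h^-1)    : 0.00269  (generating value 0.002)
R^2 growth     : 0.9993
% error growth : 5.14
Gaden class    : II
```

The growth constant and carrying capacity come back within ~1% under
2%-of-capacity measurement noise; the product coefficients are noisier
(they sit on a much smaller scale), and the mean absolute percent error
of ~5% matches what one expects from this noise level. Both α and β are
materially nonzero, so lipid production is partially growth-associated
(Gaden Class II).

The same pipeline from the shell:

```sh
phycofit synth --preset "C. salina N+" --seed 1 -o run.csv
phycofit fit run.csv -o results.json
phycofit classify --alpha 0.125 --beta 0.002     # -> II
phycofit assay chlorophyll --od665 1.0           # -> 13.43
```

Estimators follow the scikit-learn protocol (`LogisticGrowthModel`,
`LuedekingPiretModel`: `fit`/`predict`/`get_params`) and compose with
sklearn tooling; `fit_logistic`, `fit_luedeking_piret` and
`fit_condition` are thin functional wrappers.

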