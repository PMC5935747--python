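# sigrow

Sigmoidal growth-curve modelling for crop biomass: forward evaluation,
global least-squares fitting, and AIC model comparison of two
four-parameter growth models, built statsmodels-style (a model object
constructed from data whose `fit()` returns a results object).

## The problem

Crop biomass over a growing season follows a sigmoid: a slow start, a
log-phase, and a plateau at maturity. Two quantities of agronomic interest
fall straight out of a fitted curve — the **maximum biomass** `w_max`
(a yield proxy) and the **time to maturity** `t_e`. Classical sigmoids
(logistic, Gompertz, Richards) treat `w_max` as an asymptote that the
trajectory never actually reaches; the two models here instead reach their
maximum at a finite, estimable time `t_e`, so `w_max = w(t_e)`.

**NSG** (new sigmoidal growth) defines the growth *rate* by squaring a
Ratkowsky-type square-root relation transplanted from the temperature axis
to the time axis,

```
r(t) = c² (t − t_b)² (1 − e^{k(t − t_e)})²,
```

and obtains biomass as the closed-form integral of `r` from the growth
start `t_b` (see `docs/methods.md` for the expression). **BSG** (beta
sigmoidal growth) is the flexible beta-function growth curve

```
w(t) = c_m (t − t_b) · (2t_e − t_m − t)/(2t_e − t_m − t_b)
       · ((t − t_b)/(t_m − t_b))^{(t_m − t_b)/(t_e − t_m)},
```

with maximum growth rate `c_m` at time `t_m`. Fitting is seeded
differential evolution inside a data-driven parameter box, refined by
Nelder–Mead (plus a profile refinement along the weakly identified NSG `k`
direction); models are ranked by AIC. The package ships the published
parameter sets of eight crop species (sunflower, peanut, black soybean,
garden pea, adzuki bean, mung bean, cotton, sweet sorghum) as fixtures,
plus a seeded synthetic-data generator and recovery/selection experiment
harnesses, since the original field datasets are not publicly available.

Intended users: agronomists and modellers fitting biomass (or comparable
determinate-growth) trajectories, and anyone needing a tested reference
implementation of these two curves.

## Worked example

```python
import sigrow as sg

# published adzuki-bean NSG parameters -> synthetic noisy season
fx = sg.crop_fixture("adzuki bean")
series = sg.simulate_series(
    fx.nsg_params,
    noise=sg.NoiseModel("proportional", 0.02, seed=42),
    label="adzuki bean (synthetic)",
)
report = sg.compare_models(series, seed=42)
print(report.summary())
```

prints

```
NSG growth model fit [adzuki bean (synthetic)]
----------------------------------------------
  n_obs: 30    seed: 42    converged: True
     c =       -0.021
     k =        0.535
   t_b =       13.773
   t_e =       71.162
  SSE  = 0.219855 g^2
  R^2  = 0.9999
  AIC  = -139.48  (sse)
  w_max = 23.76 g at t_e = 71.16 d

BSG growth model fit [adzuki bean (synthetic)]
----------------------------------------------
  n_obs: 30    seed: 42    converged: True
   c_m =        0.966
   t_m =       62.659
   t_b =      -40.346
   t_e =       73.384
  SSE  = 1.10892 g^2
  R^2  = 0.9994
  AIC  = -90.93  (sse)
  w_max = 24.51 g at t_e = 73.38 d
  note: maturity estimate extrapolates beyond the observed time span: ...

delta AIC (NSG - BSG) = -48.55  --> preferred model: NSG
```

Reading: the data were generated from the adzuki-bean NSG row (true
`t_e = 71.43` d, `w_max = 23.57` g) with 2% proportional noise; the NSG
refit recovers maturity within a third of a day and the maximum biomass
within 1%, and the AIC difference of −48.5 decisively prefers the
generating model. Both fits have R² > 0.999 — goodness of fit alone does
not separate the models; the AIC does.

The same workflow is available from the shell:

```
sigrow fixtures                                   # the eight bundled crops
sigrow simulate --species "adzuki bean" --model nsg \
       --noise proportional --seed 42 --out adzuki.csv
sigrow fit adzuki.csv --model both --seed 42
sigrow recover --species sunflower --replicates 20 --seed 1
```

Series files are plain CSV (`time,biomass`; TSV via `--delimiter`).

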