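# esmvar

Two-level Bayesian VAR(1) dynamic structural equation modelling for
quarter-hourly experience-sampling (e-diary) data, built around a concrete
clinical question: do increases in negative affective arousal precede drops
in momentary self-esteem — and is that temporal coupling specific to
borderline personality disorder (BPD), compared with depressive disorders
(DD) and non-clinical controls (NCC)?

The package is aimed at researchers analysing intensive longitudinal data:
it covers the whole path from raw time-stamped e-diary responses to
hypothesis verdicts, and ships a synthetic-data generator that emulates the
full study design so every stage is testable without any data download.

## The model

Each observed rating vector `y_it = (arousal, self-esteem)` for person *i*
at occasion *t* is decomposed into a latent trait and a within-person state,

```
y_it = mu_i + w_it
w_it = Phi_i w_{i,t-1} + zeta_it ,   zeta_it ~ N(0, Sigma_i)
```

with a person-specific transition matrix

```
Phi_i = [ phi_A,i      phi_AonS,i ]      (AR(1) of arousal, self-esteem -> arousal)
        [ phi_SonA,i   phi_S,i    ]      (arousal -> self-esteem, AR(1) of self-esteem)
```

and a person-specific innovation covariance parameterised by log variances
and a Fisher-z innovation correlation. The nine person effects

```
eta_i = (mu_A, mu_S, phi_A, phi_S, phi_SonA, phi_AonS, ln sig2_A, ln sig2_S, z_AS)
```

are multivariate normal at level 2, `eta_i ~ N(gamma + beta * x_i, Omega)`,
where `x_i` is an optional person-level predictor (the raw diagnostic group
code 1/2/3, or a 0/1 dummy for pairwise contrasts). Estimation is a Gibbs
sampler with missing-data augmentation (missing prompts are latent
variables drawn from their conditional normal each sweep), conjugate
normal blocks for slopes, means and fixed effects, an adaptive Metropolis
block for the innovation parameters, and an inverse-Wishart block for
`Omega`. Convergence is monitored with the Gelman–Rubin potential scale
reduction factor (cutoff 1.10); summaries are posterior medians with
equal-tailed 95% credible intervals, and a parameter is called
"significant" when its interval excludes zero.

Key temporal quantities: `gamma_phi_se_on_arousal_lag` is the average
arousal(t) → self-esteem(t+1) cross-lagged effect (the affect-drives-self-esteem
hypothesis); `gamma_phi_arousal_on_se_lag` is the reverse.

## Worked example

```python
from esmvar import (McmcConfig, default_missingness, default_true_params,
                    summarize, fit_dsem)
from esmvar.simulate import generate_dataset

# 42 + 40 + 40 persons, 52 quarter-hourly prompts, ~50% time-of-day missingness
params = default_true_params("study")
data = generate_dataset(params, default_missingness(52, 0.5), seed=11)

bpd = [g for g in data["grids"] if g.group == 1]
cfg = McmcConfig(n_chains=2, n_iterations=1200, n_burn_in=500, seed=5)
s = summarize(fit_dsem(bpd, config=cfg))
print(s.loc[["gamma_mu_arousal", "gamma_phi_arousal",
             "gamma_phi_se_on_arousal_lag"]].round(3))
```

prints (this exact run)

```
                             median  ci_low  ci_high    psr  significant
parameter
gamma_mu_arousal              5.825   5.571    6.081  1.002         True
gamma_phi_arousal             0.456   0.343    0.559  1.000         True
gamma_phi_se_on_arousal_lag  -0.127  -0.222   -0.020  0.999         True
```

i.e. on a cohort simulated in the BPD regime the model recovers a trait
arousal near 5.8 on the 0–10 scale, arousal inertia of about 0.46 per 15
minutes, and a significant negative arousal → self-esteem cross-lag near
the generative −0.15: momentary arousal above a person's daily average
predicts lower self-esteem at the next prompt.

The same pipeline is scriptable from the shell:

```
esmvar simulate --seed 11 --out sim/
esmvar preprocess --input sim/responses.csv --out pre/
esmvar fit --input pre/analysis_grid.csv --seed 5 --out fit/
esmvar report --fit-dir fit/ --preprocess-dir pre/ --out report.md
```

`fit` writes one Table-style summary per model (group-predictor model plus
three per-group models), a PSR report, the two-item multilevel reliability
and a machine-readable H1/H2/H3 hypothesis roll-up.

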