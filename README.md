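# gardenhunt

Camera-trap abundance modelling and interview-based hunting-scope analysis
for savanna–forest mosaics, built around the question raised by the **Garden
Hunting hypothesis**: do shifting-cultivation gardens (*conucos*) concentrate
small and medium game — and hunters — around them?

The package is aimed at wildlife ecologists and ethnozoologists who have
(a) camera-trap photo records with deployment logs and per-site covariates,
and (b) semi-structured interview data on hunting scope. It reimplements the
full analysis chain as a tested, reusable Python library, and ships a
synthetic-study generator with known truth so every stage can be validated
without field data.

## The models

**Royle–Nichols (RN) latent-abundance occupancy model.** Detection
heterogeneity is driven by latent site abundance: with `N_i ~ Poisson(λ_i)`
animals at site *i* and per-individual, per-visit detection probability
`r_ij`, the probability of detecting the species at all on visit *j* is

    p_ij = 1 − (1 − r_ij)^{N_i}

with `log λ_i = x_i·β` (site covariates: standardized tree cover, optionally
its square, distances to river and conuco) and `logit r_ij = w_ij·α`
(observation covariates: survey effort, standardized visit date,
inverse-distance track density). The likelihood marginalizes `N_i` over
`0..K`; fitting is multi-start quasi-Newton with an exact analytic score.

**Multimodel inference.** All candidate models (effort always retained on
the detection side; 32 models for a linear tree-cover effect, 48 with a
quadratic term) are ranked by AICc — or QAICc when the parametric-bootstrap
Pearson-χ² goodness of fit indicates overdispersion (ĉ = observed χ² /
bootstrap mean > 1, in which case SEs and CIs are inflated by √ĉ).
Variable importance is the sum of Akaike weights over models containing a
term; coefficients are conditionally model-averaged over the Δ(Q)AICc ≤ 10
subset.

**Hunting-scope indexes.** From interview citations,
`Hv = (h/n)·N` (importance) and `Pv = (p/n′)·N′` (first-choice preference,
computed over respondents expressing any preference).

**Hunting-site selection.** Logistic regression of hunting occurrence on
raw-scale covariates, Pearson χ² contingency tests of habitat/season
preferences across communities, and a descriptive comparison of predicted
abundance at hunted vs unhunted sites.

## A worked example

```python
import numpy as np, pandas as pd
from gardenhunt.rn import fit_rn
from gardenhunt.simulate import simulate_species_history
from gardenhunt.survey import standardize

rng = np.random.default_rng(1)
cov = pd.DataFrame({                     # 54 sites, bimodal tree cover
    "camera_id": [f"C{i:02d}" for i in range(54)],
    "tree_buffer": standardize(np.r_[rng.normal(15, 4, 27),
                                     rng.normal(75, 6, 27)]),
    "dist_river": standardize(rng.lognormal(6.3, 0.8, 54)),
    "dist_conuco": standardize(rng.lognormal(6.865, 1.0, 54)),
    "track_dens": standardize(rng.normal(0, 1, 54))})
history, spec = simulate_species_history(
    cov, {"intercept": -1.0, "effort": 0.5},
    {"intercept": 0.7, "tree_buffer": 1.0}, rng)
fit = fit_rn(spec, history, cov, seed=0)
```

Running `python examples/02_rn_model.py` (the same computation) prints:

```
simulated history: 54 sites x 9 visits, 275 detections
converged: True   log-likelihood -177.62   K=135
  p:(Intercept)    -1.098 (SE 0.469)   truth -1.00
  p:effort         +0.726 (SE 0.455)   truth +0.50
  lam:(Intercept)  +0.920 (SE 0.195)   truth +0.70
  lam:tree_buffer  +0.816 (SE 0.123)   truth +1.00
predicted lambda: median 2.80, range 0.85-7.83
```

Each coefficient lands within ~2 SE of the generating value: abundance
rises about e¹ ≈ 2.7× per SD of tree cover, and per-individual
detectability is roughly logistic(−1.1 + 0.73·effort). The remaining
`examples/` scripts walk through event collapsing and the
frequency-of-detection index, candidate-set selection with GOF, the
Hv/Pv indexes (including the sum-to-N identity), the hunting-selection
regressions, and the end-to-end pipeline (`gardenhunt run --preset
gran-sabana`).

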