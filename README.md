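# envineq

Spatio-temporal ecological regression for environmental health-inequality
analysis on areal city data.

Two questions drive the package.  **Differential exposure:** are a city's
deprived neighborhoods exposed to higher levels of environmental hazards
(air pollution, traffic noise) than affluent ones?  **Differential
susceptibility:** does the same exposure produce larger mortality effects
in deprived neighborhoods?  Both are confounded by the *change-of-support*
problem — pollutants are measured at a handful of monitoring stations and
noise only as 5-dB isoline bands, while deaths are counted on
neighborhoods — and by spatio-temporal dependence in small-area counts.

`envineq` is written for epidemiologists and biostatisticians who want a
tested, fully reproducible implementation of this analysis: a
synthetic-city generator supplies data with the exact generative structure
the models assume, so every stage is validated end to end without any
external download, and real city data can be substituted later through the
documented CSV/GeoJSON formats.

## The model

For each sex, neighborhood *i* and year *t*:

```
O_it ~ Poisson(mu_it · Pop_it)

log mu_it = Σ_q β_q HI_q,it + γ₁ Pollutant_it + Σ_l γ₂,l Noise_l,it
          + Σ_q ω_q HI_q,it : Hazard_it + θ' z_it
          + δ₁ Pop4564_it + δ₂ Pop65_it + S_i + α_i + T_t + η_it
```

with yearly income quintiles `HI_q` (first quintile reference), hazard ×
quintile interactions `ω`, socioeconomic and land-use covariates `z`, the
age-structure regressors that resolve the mutual-standardization problem,
a Matérn GMRF spatial effect `S`, iid area heterogeneity `α`, an RW1
yearly trend `T` and an iid space-time interaction `η`.  Precision
hyperparameters carry penalised-complexity priors.  A summary form
replaces the individual hazards with a binary *polluted-neighborhood*
indicator (predicted hazard levels in the top two yearly quintiles), whose
quintile interactions `ω_q` measure differential susceptibility.

Upstream, station records are kriged to neighborhood centroids with a
Matérn(ν = 3/2) Gaussian process (planar GLS trend, penalized maximum
marginal likelihood), noise bands are aggregated by area-weighted band
midpoints, and exposure uncertainty is propagated into the health model by
likelihood-tilted resampling of joint exposure draws — the plug-in
posterior-mean exposure demonstrably attenuates hazard coefficients when
stations are few and noisy.  Inference is a Laplace scheme for the latent
Gaussian Poisson model (empirical Bayes with a Kass–Steffey covariance
correction), with a Metropolis-within-Gibbs sampler as the cross-check
route.  `docs/methods.md` has the details and the design rationale.

## Worked example

Generate a synthetic city in which deprived neighborhoods are more exposed
(income gradient −2 on the pollutant surface) and more susceptible
(polluted-neighborhood RR 1.3, 5th-quintile interaction RR 0.7), then run
the analysis:

```python
import numpy as np, pandas as pd
import envineq as ei
from envineq.design import ModelSpec
from envineq.inequality import assess_exposure_gradient, fit_susceptibility, polluted_indicator
from envineq.synthetic import SimulationTruth, exposure_table

geom = ei.generate_geometry(73, seed=1)
panel = ei.generate_covariates(geom, 8, seed=1)
income_tab = panel[panel.sex == "male"][["area_id", "year", "income"]]

pollutant = ei.generate_exposure_fields(
    geom, 8, [ei.HazardConfig(name="no2", intercept=44.0, matern_sd=5.0,
                              income_gradient=-2.0)],
    seed=1, income=income_tab)[0]
noise = ei.generate_noise_fields(
    geom, 8, ei.HazardConfig(name="noise", intercept=62.0, matern_sd=4.0,
                             income_gradient=2.0), seed=2, income=income_tab)

truth_exposures = exposure_table([pollutant, *noise], geom)
indicator = polluted_indicator(
    truth_exposures, hazards=["no2", "noise_daytime", "noise_evening", "noise_night"],
    quintile_rule="any")
truth = SimulationTruth(
    coefficients={"intercept": np.log(0.01), "income_q5": np.log(0.92),
                  "polluted": np.log(1.3), "polluted:q5": np.log(0.7)},
    spec_kwargs={"form": "polluted", "include_foreigners": False})
panel = ei.simulate_deaths(panel, indicator, truth, seed=3, geom=geom)

# exposure stage: 13 noisy stations -> GP -> centroid predictions
stations = ei.place_stations(pollutant, 13, obs_sd=2.0, seed=4)
predicted = ei.predict_centroid_exposure(ei.fit_pollutant_gp(stations, geom), geom)

# differential exposure
income = pd.Series(income_tab["income"].to_numpy(),
                   index=pd.MultiIndex.from_arrays(
                       [income_tab["area_id"], income_tab["year"]],
                       names=["area_id", "year"]))
tab = predicted.table.rename(columns={"mean": "no2"})[["area_id", "year", "no2"]]
gradient = assess_exposure_gradient(tab, income, "no2")

# differential susceptibility
spec = ModelSpec(sex="male", form="polluted", include_foreigners=False)
report = fit_susceptibility(panel, indicator, spec, geom=geom, seed=5)
```

Output (printed by the snippet's `print` statements):

```
Kruskal-Wallis H = 109.3 (df 4), p = 1.05e-22; smooth edf 9.8, p = 1.86e-27, slope -
polluted     RR 1.330 (1.271–1.392)
income_q5    RR 1.022 (0.911–1.146)
polluted:q5  RR 0.672 (0.613–0.736)
```

Reading it: the Kruskal–Wallis test rejects equality of predicted NO₂
levels across income quintiles and the spline smooth slopes downward —
deprived neighborhoods are more exposed, as generated.  The
polluted-neighborhood main effect recovers the generative RR 1.3, and the
5th-quintile interaction recovers RR 0.7: mortality in polluted
neighborhoods is about 33% lower for the most affluent quintile than for
the most deprived — the differential-susceptibility signature.

A command-line pipeline wraps the same stages
(`envineq simulate | fit-exposure | assess-exposure | fit-health |
assess-susceptibility | report`, each taking `--config config.yaml`), with
seeded determinism and provenance records per stage.

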