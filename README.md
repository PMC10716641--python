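# fincee

Analysis pipeline for **fin whale behavioural responses to mid-frequency
active sonar (MFAS)**, measured in controlled exposure experiments (CEEs).
A CEE tags a whale, records a 30-min pre-exposure baseline, then projects
MFAS or pseudorandom-noise (PRN) signals every 25 s for 30 min — ramping
the source level in 3 dB steps from 160 dB up to 210 dB (MFAS) or 206 dB
(PRN) re 1 µPa·m — followed by a 30-min post-exposure phase; control CEEs
run the same timeline silently.  The package implements the three
complementary analyses used to quantify responses in such experiments,
exercised end to end on synthetic data plus the study's published summary
tables (packaged as CSV fixtures):

1. **Context hidden Markov model** (the core model).  Each dive yields an
   observation vector *(dive time, max depth, lunge count, speed over
   ground, turning angle)* with gamma/gamma/Poisson/gamma/von Mises
   emissions conditional on an N-state hidden chain (N = 3: deep feeding,
   non-feeding, shallow feeding).  Two extensions: discrete random-effect
   **contexts** — each whale follows one of K latent state-switching
   regimes with mixing probabilities π_k — and **exposure covariates on
   transitions**, γ_ij ∝ exp(η_ij + β_ij·x) with the diagonal as
   multinomial-logit reference, where x is an exposure measure (binary
   flag, CEE phase, or a received-level covariate) for each dive.
   Maximum likelihood over all whales (mixture log likelihood via the
   forward algorithm, exact analytic score, multi-start quasi-Newton),
   AIC selection over K / covariate / sharing, Wald intervals from the
   observed information, and mixture-weighted local decoding.
2. **PCA + penalized additive models** (group level).  Correlation-matrix
   PCA per metric category; axes explaining > 10% variance are modelled as
   `axis ~ treatment status × type + behavioural state + s(max RL)
   + s(cSEL) + s(avg RL)` with a ridge-penalized whale intercept,
   GCV-chosen penalties and approximate F term tests.
3. **Severity survival analysis** (individual level).  Expert severity
   scores per CEE become recurrent-event survival data with cumulative
   sound exposure level (cSEL, dB re 1 µPa²·s) as the "time" axis:
   stratified Cox proportional-hazards models (low 1–3 / moderate 4–6
   severity bands, Breslow ties, grouped-jackknife SEs), a
   scaled-Schoenfeld proportional-hazards test, and dose–response curves
   1 − S(cSEL) from the Breslow baseline hazard.  Mahalanobis-distance
   series quantify within-whale multivariate change against baseline.

A `synthetic` module generates every input the analyses need — ping
schedules, received levels by spherical spreading, dive sequences from a
known context HMM, sampled tag series — so the whole chain is testable
without any field data.

## Worked example

```python
import numpy as np
from fincee import synthetic, hmm
from fincee.pipeline import default_generator_params

# exposure covariate: zero before/after, positive during the CEE
x = np.concatenate([np.zeros(60), np.full(30, 1.2), np.zeros(60)])
params = default_generator_params(3, k_contexts=2, beta_21=1.5)
# beta_21 puts the exposure effect on the non-feeding -> deep-feeding logit
data, truth = synthetic.simulate_dives(params, x, n_whales=25,
                                       dives_per_whale=150, seed=42)
fit = hmm.fit_hmm(data, hmm.HMMSpec(n_states=3, n_contexts=2,
                                    covariate="custom"), n_starts=1, seed=0)
print(round(fit.loglik, 1), fit.n_parameters, round(fit.aic, 1))
print(np.round(fit.params.depth_shape / fit.params.depth_rate, 1))
```

prints

```
-53531.7 50 107163.4
[179.2  49.1  15. ]
```

— the fitted log likelihood, parameter count and AIC, and the three
states' mean maximum depths (truth: 180, 50 and 15 m; states are labelled
deepest-first).  Decoding this fit with `hmm.local_decode` shows switches
from the non-feeding into the deep-feeding state jumping from 15% of
opportunities before exposure to 55% during it — the qualitative response
pattern the transition covariate encodes.

The survival stage runs directly off the packaged severity table:

```python
from fincee import severity, synthetic
tab = synthetic.load_study_tables()
events = severity.build_event_table(tab.severity_table)
null = severity.fit_hazards(events, None)
sig = severity.fit_hazards(events, ["signal_type"])
print(round(null.aic, 2), round(sig.aic, 2), round(abs(null.aic - sig.aic), 3))
print(round(severity.ph_test(sig).global_p, 3))
```

prints

```
46.38 46.02 0.364
0.187
```

— the null and signal-type model AICs sit within half a unit of each
other (weak support for a signal-type effect), and the proportional
hazards assumption is not rejected.

A command-line interface wraps the stages
(`fincee simulate | metrics | hmm-fit | hmm-select | pca | survival |
validate | run-all`).

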