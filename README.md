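# stratddm

Mixture drift-diffusion modelling of children's arithmetic strategy
choice, switching and execution.

When children verify simple additions (`3 + 4 = 7?`) they mix strategies:
direct fact **retrieval**, **counting** up, or **decomposition** into
easier parts.  Aggregate accuracy and RT hide this mixture, and verbal
self-reports are unreliable in young children.  `stratddm` implements a
hierarchical Bayesian cognitive model that infers, from choice-coded
response times alone, which strategy was used on each trial and the
cognitive and metacognitive parameters that govern the mixture.  It is
aimed at computational cognitive modellers and developmental researchers
who want trial-level latent strategy inference with a fully testable
generative model.

## Model

Each trial starts (after non-decision time τ) as a Wiener diffusion for
retrieval with drift δ − d (retrieval efficiency minus item difficulty),
threshold α, start bias β toward the correct boundary.  If retrieval is
unresolved at the switching time s = γ + ω·d, the child continues
retrieval with probability logistic(μ − d) or restarts a fresh
accumulator with the counting drift κ − λ·d, or the decomposition drift
κ − λ·d − Δ.  Trials unresolved at the deadline T_max are censored.  The
trial likelihood for decision time u > s is

    p_r f_R(u) + S_R(s) [ p_c f_C(u − s) + p_d f_D(u − s) ]

with f and S the Wiener first-passage density and survival function.
Posterior strategy *responsibilities* per trial yield derived
metacognitive measures: mean selection entropy Ω, its SD Σ, adaptivity ψ
(correlation between retrieval drift and retrieval use), and strategy-use
proportions; between-session stability is quantified with two-way ANOVA
ICCs.  Estimation is by blocked adaptive Metropolis-within-Gibbs over
person-session, person, item and group levels.  See `docs/methods.md`
for the full specification and design rationale.

## Worked example

Simulate a small cohort, score every trial against the generating
session-level parameters, and summarize each child:

```python
from stratddm.simulate import simulate_cohort, default_group_params
from stratddm.likelihood import responsibilities_table
from stratddm.measures import metacog_summary
from stratddm.readwrite import RunConfig

group = default_group_params()
cohort = simulate_cohort(n_persons=6, n_sessions=2, trials_per_session=40, seed=7)
resp = responsibilities_table(cohort.observed(), cohort.sessions, cohort.items,
                              RunConfig(), group.nu, group.lam, group.Delta)
print(metacog_summary(resp, cohort.persons, cohort.items).round(3).to_string(index=False))
```

```
person_id  Omega  Sigma    psi  use_retrieval  use_counting  use_decomposition
     p000  0.461  0.249  0.312          0.369         0.556              0.075
     p001  0.520  0.270  0.235          0.431         0.484              0.085
     p002  0.282  0.257  0.043          0.255         0.653              0.092
     p003  0.283  0.193  0.071          0.134         0.771              0.095
     p004  0.368  0.362 -0.030          0.521         0.418              0.061
     p005  0.402  0.298  0.287          0.644         0.327              0.030
```

`Omega` is each child's average uncertainty over strategies (nats, max
ln 3 ≈ 1.10): p003 solves almost everything by counting with little
uncertainty, while p001 mixes strategies trial by trial.  `psi > 0`
means the child preferentially retrieves exactly those items on which
their retrieval drift is high — metacognitively calibrated strategy
choice.  The same API fits real tidy trial tables
(`person_id,session_id,item_id,rt,response`); use
`stratddm fit --trials ... --items ... --out-dir ...` for full
hierarchical posterior inference, and `stratddm simulate`,
`stratddm measures`, `stratddm validate` for the rest of the toolkit.

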