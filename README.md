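# cultrans

Generative workflow tools for cultural evolution: how do conformist social
learning and migration jointly shape *between-group cultural diversity*,
and how well can the underlying transmission parameters be recovered from
the kinds of data field researchers actually have?

The package is aimed at cultural-evolution and social-science researchers
who want to move between theory and data with an explicit generative model
at every step. It provides, as one consistent toolkit:

* **`cultrans.scm`** — a linear structural causal model over standardized
  country-level variables (age `A`, migration `M`, conformity `C`,
  diversity `D`): simulation, the backdoor-adjusted regression of `D` on
  `(M, C)`, causal contrasts between migration levels, and
  conditional-independence checks of the DAG's testable implications.
* **`cultrans.abm`** — an age-structured agent-based model: yearly
  survival `exp(-r_S·age)`, birth into fixed-size groups, pairwise-swap
  migration (scalar rate `m` or an age schedule `m_a`), innovation with
  probability `μ`, and frequency-dependent social learning in which a
  learner adopts variant `i` from 30 groupmates with probability
  `p_i ∝ n_i^θ` — unbiased copying at `θ = 1`, conformity at `θ > 1`,
  anticonformity at `θ < 1`.
* **`cultrans.diversity`** — the cultural fixation index
  `CFST = (H_T − H_S)/H_T`, the share of total variant heterogeneity that
  lies between groups.
* **`cultrans.observe`** — synthetic observation layers: a longitudinal
  panel (a cohort followed yearly with true event indicators and contact
  variants) and cross-sectional CFST snapshots, including the
  `d_unbiased` (θ=1, m=0.3) and `d_conformist` (θ=2, m=0.1) reference
  regimes.
* **`cultrans.longitudinal`** — the transmission likelihood (Bernoulli
  innovation and migration, categorical adoption with `p_i ∝ n_i^θ`),
  adaptive random-walk Metropolis posterior sampling of `(μ, θ, m_a)`,
  HPDIs, and counterfactual migration effects pushed back through the ABM.
* **`cultrans.abc`** — rejection ABC for `(θ, m)` from a single
  cross-sectional CFST value, with posterior prediction and ±10%
  migration-effect post-processing.
* **`cultrans.validation`** — simulation-based calibration of the whole
  panel-inference pipeline.

See `docs/methods.md` for model assumptions, parameter defaults, numerical
choices, and known limitations.

## A worked example

Simulate a 30-year longitudinal panel under known parameters and recover
them (`examples/longitudinal_recovery.py`):

```
$ python examples/longitudinal_recovery.py
panel: 2164 person-years, 366 individuals in wave 1, 1 in the final wave

sampler acceptance 0.43
param  mean    sd  hpdi_lo  hpdi_hi     ess
   mu 0.012 0.006    0.003    0.020 604.538
theta 1.782 0.082    1.640    1.909 473.615
  m_0 0.044 0.017    0.018    0.070 521.887
  m_1 0.168 0.016    0.141    0.192 558.856
  m_2 0.103 0.009    0.088    0.119 515.886
  m_3 0.026 0.007    0.014    0.037 434.200

true values: mu=0.01, theta=1.7, m_a=(0.05, 0.2, 0.1, 0.02)
each 90% HPDI should bracket its generating value about 9 times in 10.
m_a scaled by 1.05: mean CFST change -0.0146
m_a scaled by 0.95: mean CFST change +0.0159
```

The innovation rate `μ`, the conformity exponent `θ`, and three of the four
age-class migration rates are bracketed by their 90% intervals; `m_1` just
misses (0.2 vs [0.141, 0.192]), which is exactly what 90% intervals do
about once in ten parameters — the replicated calibration study in the test
suite confirms the nominal rate. The final two lines are the causal
estimand: scaling every age-class migration rate by ±5% and re-simulating
the metapopulation per posterior draw shifts long-run between-group
diversity symmetrically down/up.

The other example scripts each demonstrate one capability with a few lines
of output: `cfst_basics.py` (the index on hand-built populations),
`scm_adjustment.py` (confounding and backdoor adjustment),
`abm_sweep.py` (the conformity × migration diversity landscape),
`abc_crosssection.py` (likelihood-free inference from one CFST value).

A thin command line mirrors the workflow stages
(`cultrans scm|abm|cfst|observe|fit-longitudinal|abc`, each with `--seed`
and `--out`; every output directory gets a `provenance.json` sufficient to
re-run the command).

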