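# opencohort

Power and sample-size calculations for **open-cohort longitudinal cluster
randomized trials** — stepped wedge, cluster crossover and parallel designs
measured over several periods, in which each cluster contributes a constant
number of participants *m* per period but individual participants contribute
*variable* numbers of measurements: some are present throughout, others are
replaced as they leave.

Classical sample-size formulas for these designs assume either a closed
cohort (everyone measured in every period) or repeated cross-sections
(everyone measured once).  Real trials in schools, nursing homes or sampled
communities sit in between, and using either extreme misstates the power.
`opencohort` is for trial statisticians planning such studies.

## The model and the unified design effect

Outcomes follow a linear mixed model with fixed period effects β_t, a
treatment effect θ on the cluster-period treatment indicator X_kt, and
block-exchangeable random effects:

    Y_kti = β_t + θ X_kt + C_k + CP_kt + η_ki + ε_kti

parameterized by the total variance σ², the intracluster correlation ρ, the
cluster autocorrelation π and the participant autocorrelation τ.  The degree
of cohort openness enters through the **churn rate** χ(t, s): the proportion
of a cluster's period-t participants absent in period s.  Collapsing to
cluster-period means, churn attenuates only the participant term of the
between-period covariance:

    cov(Ȳ_kt, Ȳ_ks) = σ_C² + σ_η² (1 − χ(t, s)) / m

When churn is constant across period pairs, the correlation between two
cluster-period means is

    r = [m ρ π + (1 − ρ) τ (1 − χ)] / [1 + (m − 1) ρ]

and the clusters needed are K_L = DE(r) · [1 + (m − 1)ρ] · n_i / m, where
n_i is the individually-randomized sample size and DE(r) the longitudinal
design effect computed from the treatment schematic.  χ = 0 recovers the
closed-cohort formula and χ = 1 the one-measurement-per-participant formula,
so both classical results are special cases.  For non-constant churn
(e.g. rotation sampling, where χ(t, s) = min(|t−s|/p, 1)) and for
discrete-time decaying correlations, power comes from the generalized least
squares variance of θ̂ computed directly from the T×T covariance of
cluster-period means.  Both routes are implemented and agree to 1e−8
wherever both apply; a Monte-Carlo simulator verifies the analytic
covariances, variances and powers empirically.

Supported sampling schemes: core group (constant churn), closed population
(repeated simple random samples of m from M), Beta-distributed cluster-level
churn, in-for-p rotation panels, and custom per-pair churn tables.
A moment-matching conversion turns autocorrelations estimated under a
no-decay model into the per-period decay rates of the decay model.

## Worked example

A stepped wedge in 12 primary schools (three sequences of four, four
periods), 10 students per school-period, targeting a 2-point change in a
self-esteem score with σ² = 25, ρ = 0.33, π = 0.9, τ = 0.7 and a closed
cohort:

```python
import opencohort as oc

design = oc.stepped_wedge(3, (4, 4, 4), m=10)
vc = oc.BlockExchangeableComponents(sigma2=25, rho=0.33, pi=0.9, tau=0.7)
query = oc.PowerQuery(theta=2.0, alpha=0.05, target_power=0.893)
print(oc.clusters_required(design, vc, chi=0.0, q=query))
```

or, with the same trial described in a YAML config, from the shell:

```sh
$ opencohort samplesize trial.yaml
{
  "r": 0.8662468513853904,
  "design_effect": 0.11775196574130707,
  "n_individual": 256.41703420200486,
  "clusters_longitudinal": 11.98686310125629,
  "clusters_per_sequence": 4,
  "achieved_power": 0.8933230492470311
}
```

An individually randomized trial would need about 257 participants; the
clustering and longitudinal design effects turn that into 11.99 clusters,
i.e. 4 clusters per sequence, giving 89.3% power.  Openness costs power:
under in-for-p rotation sampling (`opencohort curve trial.yaml --family
in_for_p`) power falls to 65.6% when each participant is measured once
(p = 1) and reaches only 82.9% at p = 4 — never the closed-cohort 89.3%,
because some first-period participants are always rotated out.

`opencohort convert-decay -T 4 --value 0.7` converts the no-decay
participant autocorrelation 0.7 into the per-period decay rate 0.8010 for
use with the decay model.

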