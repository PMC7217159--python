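# Methods

## Statistical model

`opencohort` treats time as discrete, with periods 1..T common to all
clusters.  Each cluster follows one row of a binary sequences-by-periods
treatment schematic; every cluster-period cell contains exactly m
measurements, but the participants behind those measurements may change
between periods.  Missingness of a participant in a period is assumed
noninformative (missing at random given the participant's observed
measurements): the package does not model informative dropout, survivor
effects, participants migrating between clusters, binary outcomes,
transition periods, or unequal cluster-period sizes.

Two covariance models for a continuous outcome are supported.

**Block-exchangeable.**  Cluster, cluster-period, participant and residual
random effects with variances σ_C², σ_CP², σ_η², σ_ε², parameterized by the
total variance σ² and three correlations: intracluster ρ, cluster
autocorrelation π, participant autocorrelation τ
(σ_C² = σ²ρπ, σ_CP² = σ²ρ(1−π), σ_η² = σ²(1−ρ)τ, σ_ε² = σ²(1−ρ)(1−τ)).
At the boundary ρ = 0 the value of π is irrelevant (the cluster components
vanish identically), and likewise τ at ρ = 1; the component decomposition is
well defined even where the defining ratios are not.

**Discrete-time decay.**  Cluster-period effects whose correlation decays
as π_D^|t−s| and autoregressive participant-level error vectors with
correlation τ_D^|t−s|, parameterized by σ_D², ρ_D, π_D, τ_D.  Setting
π_D = τ_D = 1 recovers the block-exchangeable model with π = τ = 1.

Under either model, averaging within cluster-periods is lossless for the
treatment effect (outcomes are exchangeable within a period), so all
analytic results work with the T×T covariance V of cluster-period means.
The number of participants shared by periods t and s, n(t, s), enters V only
through the churn rate χ(t, s) = 1 − n(t, s)/m:

* block-exchangeable: V_ts = σ_C² + σ_η²(1 − χ(t, s))/m, diagonal
  σ_C² + σ_CP² + (σ_η² + σ_ε²)/m;
* decay: V_ts = σ_CP,D² π_D^|t−s| + (σ_εD²/m) τ_D^|t−s| (1 − χ(t, s)),
  diagonal σ_CP,D² + σ_εD²/m.

When cluster-level churn is random, only its expectation enters V, so all
analytic paths use expected churn.

## Sampling schemes

* **Core group** (constant churn χ): a fixed core of m(1−χ) participants
  present in every period, topped up with single-measurement participants.
* **Closed population**: an independent simple random sample of m from a
  pool of M each period; E[χ] = 1 − m/M and the expected pairwise overlap is
  m²/M.  Participants may reappear after absence.
* **Beta churn**: cluster k's churn drawn once as χ_k ~ Beta(α, β) with
  α + β = m (α the expected number lost, β retained per period), then
  realized as that cluster's core-group structure.  Drawing once per cluster
  rather than per period pair is a design choice; only E[χ_k] = α/(α+β)
  affects covariances either way.
* **In-for-p rotation**: each participant measured in at most p consecutive
  periods, 1/p of the sample replaced each period; χ(t, s) =
  min(|t−s|/p, 1).  When p does not divide m the rotation groups have sizes
  ⌊m/p⌋ or ⌈m/p⌉, the extra slots assigned deterministically to the
  longest-tenure starting groups; realized overlaps come from the realized
  panels, not the ideal fractions.
* **Custom**: an arbitrary symmetric per-pair churn table.  It is validated
  by building the implied covariance and checking positive semidefiniteness
  (minimum eigenvalue ≥ −1e−10, relative); no repair is attempted.

Any realizable membership satisfies, for every triple of periods,
n(t, u) + n(u, s) ≤ n(t, s) + m.  Matrices produced by the panel
constructions satisfy it by construction and are checked exhaustively on
creation; rounded custom tables may fail it, which raises an error.
Non-integer core sizes m(1−χ) are rounded half up; rounding affects only
simulation — the analytic path uses the real-valued churn.

## Power calculations

Two independent routes are implemented.

**Design effect** (constant churn only).  r = [mρπ + (1−ρ)τ(1−χ)] /
[1 + (m−1)ρ] is the correlation between two cluster-period means of the same
cluster; DE(r) is the longitudinal design effect computed from the
schematic's treatment totals; required clusters are
K_L = DE(r)[1 + (m−1)ρ] n_i / m with n_i = 4σ²(z_{1−α/2} + z_{1−β})²/θ*².
K_L/S is rounded up to integer clusters per sequence and the achieved power
at the integer allocation is reported alongside the real-valued K_L, so the
rounding cost is visible.  DE(r) is invariant under replicating clusters
within sequences, so evaluating it on the expanded per-cluster matrix and on
the schematic are equivalent.

**GLS variance** (any scheme/model).  The variance of the generalized
least-squares estimator of θ with fixed categorical period effects and known
V, computed from per-cluster treatment vectors.  Period effects are
categorical and fixed; the variance is invariant to reparameterizations of
the time trend.  A condition-number guard at 1e12 raises rather than
returning noise from a numerically singular V; designs with no treatment
contrast raise a singular-design error.

Power uses the normal approximation Φ(|θ*|/SE − z_{1−α/2}); the
opposite-tail term is negligible at practical powers and its omission keeps
the formula consistent with the z-based n_i.  The two routes agree to 1e−8
across a parameter grid (a core regression test); a brute-force oracle that
inverts the full KT×KT fixed-effects information matrix pins the GLS
variance to 1e−10.

## Decay adjustment

Autocorrelations estimated under a no-decay model absorb any decay present
in the data, so they cannot be plugged into the decay model directly.  The
conversion equates the total of all T² pairwise correlations:
find x ∈ [0,1] with T + 2Σ_{d=1}^{T−1}(T−d)x^d = value·T(T−1) + T.  The
left side rises strictly from T to T², so the root exists and is unique; it
is found by bracketing root search (Brent) on [0, 1] to tolerance 1e−12,
with 0 and 1 returned exactly as fixed points.  The conversion is an
explicit, separately invoked step (`convert-decay`), never applied silently,
and an inverse is provided; the round trip is exact to 1e−9.  The grouped
left-hand side is an algebraic regrouping of the double sum over period
pairs; both forms are cross-checked in tests.

## Simulator

The simulator generates participant-level outcomes under either model with
membership drawn from the scheme's panel construction (custom churn tables
have no canonical participant-level realization and are not simulated).
Under the block-exchangeable model each participant's random effect η is
drawn once and reused across their periods; under the decay model there is
no participant random effect — within-participant dependence lives entirely
in the error vector, drawn over each participant's observed periods from the
corresponding submatrix of the decay correlation matrix (a symmetric
eigenvalue square root is used so that decay rates of exactly 1 remain
simulable).  Period effects default to zero — GLS power is invariant to
them — and are overridable for data realism.

Estimation on simulated data uses the known-covariance GLS estimator, i.e.
exactly the estimator the analytic results describe; the simulator verifies
those results, it does not study mixed-model fitting (no REML).  One global
seed is split into independent per-replicate, per-cluster streams, so adding
replicates never changes earlier ones and identical spec + seed gives a
byte-identical dataset.

What the simulation checks do and do not show: they confirm that the
analytic covariance matrices, estimator variance, type-I error and power are
correct *under the stated models and schemes*.  They do not probe
informative dropout, model misspecification, estimated (rather than known)
covariance parameters, or small-sample inference — all outside scope.

## Problem sizes and numerical choices

The verification suite uses the 12-cluster, 4-period stepped wedge
configuration of the worked example with 2,000–5,000 Monte-Carlo replicates
(covariance checks pool three independent clusters at 5,000 replicates),
comparing every empirical quantity to its analytic value within three
Monte-Carlo standard errors; these sizes make the whole suite run in well
under a minute while keeping the 3-SE bands tight enough to detect a
misimplemented variance component.  Membership validity is checked over
1,000 realizations per scheme.  Covariance positivity tolerates eigenvalues
down to −1e−10 (floating-point slack only).

## Known limitations

Constant m per cluster-period; three named schemes plus custom tables
(rotation schemes with gaps — in for p, out for p′ — must be expressed as
custom tables, and then cannot be simulated); continuous-time correlation
structures, treatment-effect heterogeneity, cost optimization and
non-continuous outcomes are out of scope.  The sample-size search assumes
equal clusters per sequence.
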