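"""Monte-Carlo simulation of open-cohort trials.

Generates participant-level outcomes under either the block-exchangeable
model (cluster, cluster-period and participant random effects plus
independent errors) or the discrete-time decay model (cluster-period effects
with geometrically decaying between-period correlation, and autoregressive
participant-level error vectors), with membership realized from a sampling
scheme.  The simulator exists to verify the analytic covariance, variance
and power results empirically; estimation on simulated data uses the
known-covariance GLS estimator, which is the estimator those results
describe.

Participants absent in a period simply contribute no record (missingness is
noninformative); each participant's random effect / error vector is drawn
once and follows them across the periods in which they appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .components import BlockExchangeableComponents, DecayComponents
from .covariance import cov_matrix
from .designs import TrialDesign, expand_to_clusters
from .power import gls_variance
from .schemes import realize_panels

__all__ = [
    "SimulationSpec",
    "simulate_trial",
    "simulate_cluster_period_means",
    "simulate_theta_hats",
    "empirical_power",
    "gls_estimator_weights",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one trial design repeatedly."""

    design: TrialDesign
    components: BlockExchangeableComponents | DecayComponents
    scheme: object
    theta: float = 0.0
    beta_t: np.ndarray | None = None
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        T = self.design.n_periods
        beta = (np.zeros(T) if self.beta_t is None
                else np.asarray(self.beta_t, dtype=float))
        if beta.shape != (T,):
            raise ValueError(f"beta_t must have length {T}, got {beta.shape}")
        beta.setflags(write=False)
        object.__setattr__(self, "beta_t", beta)
        if int(self.replicates) < 1:
            raise ValueError("need at least one replicate")
        object.__setattr__(self, "replicates", int(self.replicates))


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _sqrt_psd(M: np.ndarray) -> np.ndarray:
    """Symmetric square root, tolerating rank deficiency (e.g. decay rate 1)."""
    w, U = np.linalg.eigh(M)
    return U * np.sqrt(np.clip(w, 0.0, None))


def _cluster_values_be(vc: BlockExchangeableComponents, panels, m, T, rng):
    """Per-period (m,) outcome arrays (random part only), block-exchangeable."""
    sd_c = math.sqrt(vc.sigma2_c)
    sd_cp = math.sqrt(vc.sigma2_cp)
    sd_eta = math.sqrt(vc.sigma2_eta)
    sd_eps = math.sqrt(vc.sigma2_eps)
    C = rng.normal(0.0, sd_c) if sd_c > 0 else 0.0
    CP = rng.normal(0.0, sd_cp, size=T) if sd_cp > 0 else np.zeros(T)
    all_ids = np.unique(np.concatenate(panels))
    eta = rng.normal(0.0, sd_eta, size=len(all_ids))
    values = []
    for t in range(T):
        idx = np.searchsorted(all_ids, panels[t])
        eps = rng.normal(0.0, sd_eps, size=m)
        values.append(C + CP[t] + eta[idx] + eps)
    return values


def _cluster_values_decay(vc: DecayComponents, panels, m, T, rng, chol_cache):
    """Per-period (m,) outcome arrays (random part only), decay model.

    The cluster-period effect vector has covariance sigma2_cp * pi_d^|t-s|;
    each participant's error vector, restricted to their observed periods,
    has covariance sigma2_eps * tau_d^|t-s| on that submatrix.
    """
    key_cp = ("cp",)
    if key_cp not in chol_cache:
        lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        chol_cache[key_cp] = _sqrt_psd(vc.sigma2_cp * vc.pi_d ** lags)
        chol_cache["lags"] = lags
    CP = chol_cache[key_cp] @ rng.standard_normal(T)

    periods_of = {}
    for t, ids in enumerate(panels):
        for i in ids:
            periods_of.setdefault(int(i), []).append(t)
    values = [np.empty(m) for _ in range(T)]
    pos_in_period = [dict(zip(map(int, ids), range(m))) for ids in panels]
    lags = chol_cache["lags"]
    for pid in sorted(periods_of):
        P = periods_of[pid]
        key = tuple(P)
        if key not in chol_cache:
            sub = vc.sigma2_eps * vc.tau_d ** lags[np.ix_(P, P)]
            chol_cache[key] = _sqrt_psd(sub)
        eps = chol_cache[key] @ rng.standard_normal(len(P))
        for j, t in enumerate(P):
            values[t][pos_in_period[t][pid]] = CP[t] + eps[j]
    return values


def _cluster_values(spec: SimulationSpec, panels, rng, chol_cache):
    m, T = spec.design.m, spec.design.n_periods
    if isinstance(spec.components, BlockExchangeableComponents):
        return _cluster_values_be(spec.components, panels, m, T, rng)
    return _cluster_values_decay(spec.components, panels, m, T, rng, chol_cache)


def simulate_trial(spec: SimulationSpec) -> pd.DataFrame:
    """Simulate one trial and return it in long format.

    Columns: cluster, period (both 1-based), participant (id stable across
    periods within a cluster), treatment, outcome.  Exactly m records per
    cluster-period.  Identical spec and seed give an identical frame.
    """
    design = spec.design
    Xc = expand_to_clusters(design)
    m, T = design.m, design.n_periods
    streams = [np.random.default_rng(s)
               for s in _seed_seq(spec.seed).spawn(design.n_clusters)]
    chol_cache: dict = {}
    frames = []
    for k, rng in enumerate(streams):
        panels = realize_panels(spec.scheme, m, T, rng)
        values = _cluster_values(spec, panels, rng, chol_cache)
        for t in range(T):
            y = spec.beta_t[t] + spec.theta * Xc[k, t] + values[t]
            frames.append(pd.DataFrame({
                "cluster": k + 1,
                "period": t + 1,
                "participant": np.asarray(panels[t], dtype=np.int64),
                "treatment": int(Xc[k, t]),
                "outcome": y,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_cluster_period_means(spec: SimulationSpec,
                                  replicates: int | None = None,
                                  seed=None) -> np.ndarray:
    """Simulate cluster-period mean outcomes; returns (replicates, K, T)."""
    design = spec.design
    Xc = expand_to_clusters(design)
    m, T, K = design.m, design.n_periods, design.n_clusters
    R = replicates if replicates is not None else spec.replicates
    root = _seed_seq(spec.seed if seed is None else seed)
    fixed = spec.beta_t[None, :] + spec.theta * Xc
    chol_cache: dict = {}
    out = np.empty((R, K, T))
    for rep, ss in enumerate(root.spawn(R)):
        for k, child in enumerate(ss.spawn(K)):
            rng = np.random.default_rng(child)
            panels = realize_panels(spec.scheme, m, T, rng)
            values = _cluster_values(spec, panels, rng, chol_cache)
            out[rep, k] = [v.mean() for v in values]
    out += fixed[None, :, :]
    return out


def gls_estimator_weights(design: TrialDesign, V: np.ndarray):
    """Weights w_k with theta_hat = sum_k w_k . ybar_k, plus var(theta_hat).

    Derived from the information matrix of the fixed effects (T period
    effects and the treatment effect) under known covariance V common to all
    clusters; the variance equals :func:`gls_variance`.
    """
    Xc = expand_to_clusters(design).astype(float)
    K, T = Xc.shape
    Vi = np.linalg.inv(V)
    s = Xc.sum(axis=0)
    A = np.empty((T + 1, T + 1))
    A[:T, :T] = K * Vi
    A[:T, T] = A[T, :T] = Vi @ s
    A[T, T] = np.einsum("kt,ts,ks->", Xc, Vi, Xc)
    Ainv = np.linalg.inv(A)
    a_beta, a_theta = Ainv[T, :T], Ainv[T, T]
    W = (a_beta[None, :] + a_theta * Xc) @ Vi
    return W, float(Ainv[T, T])


def simulate_theta_hats(spec: SimulationSpec, replicates=None, seed=None) -> np.ndarray:
    """GLS treatment-effect estimates across simulated replicates, using the
    analytic (true) covariance of cluster-period means."""
    V = cov_matrix(spec.components, spec.scheme,
                   spec.design.m, spec.design.n_periods)
    W, _ = gls_estimator_weights(spec.design, V)
    means = simulate_cluster_period_means(spec, replicates, seed)
    return np.einsum("kt,rkt->r", W, means)


def empirical_power(spec: SimulationSpec, alpha: float = 0.05):
    """Monte-Carlo rejection rate of the two-sided level-alpha Wald test.

    Each replicate's theta_hat uses the known-covariance GLS estimator with
    its analytic standard error.  Returns (power estimate, binomial SE).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    var = gls_variance(spec.design,
                       cov_matrix(spec.components, spec.scheme,
                                  spec.design.m, spec.design.n_periods))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    th = simulate_theta_hats(spec)
    reject = np.abs(th) / math.sqrt(var) > z
    p = float(reject.mean())
    return p, math.sqrt(p * (1.0 - p) / len(th))
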