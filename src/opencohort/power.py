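"""Power and sample size for open-cohort longitudinal cluster randomized
trials.

Two routes to the same quantity are provided and must agree whenever both
apply:

* the design-effect route, available when churn is constant across period
  pairs: the individually-randomized sample size is inflated by the usual
  clustering design effect 1 + (m-1)*rho and by a longitudinal design effect
  DE(r), where r is the correlation between two cluster-period means of the
  same cluster;
* the GLS route, available for any covariance structure of cluster-period
  means: the variance of the generalized least squares estimator of the
  treatment effect, with fixed categorical period effects and known
  covariance, is computed directly.

Power uses the normal approximation
``Phi(|theta*|/SE - z_{1-alpha/2})``, consistent with the z-based
individually-randomized sample-size formula; the opposite-tail rejection
probability is ignored as negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .components import BlockExchangeableComponents, DecayComponents
from .covariance import cov_matrix, cov_matrix_block_exchangeable
from .designs import TrialDesign, expand_to_clusters, design_totals
from .exceptions import SingularCovarianceError, SingularDesignError
from .schemes import ConstantChurn, InForP

__all__ = [
    "PowerQuery",
    "PowerResult",
    "compute_r",
    "design_effect",
    "individually_randomized_n",
    "gls_variance",
    "gls_power",
    "power_from_design_effect",
    "clusters_required",
    "power_curve",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class PowerQuery:
    """Effect size theta (outcome units, nonzero for power calculations),
    two-sided significance level alpha, and — in sample-size mode — the
    target power."""

    theta: float
    alpha: float = 0.05
    target_power: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.target_power is not None and not 0 < self.target_power < 1:
            raise ValueError(f"target power must be in (0, 1), got {self.target_power}")


@dataclass(frozen=True)
class PowerResult:
    """Output of a sample-size calculation.

    ``clusters_longitudinal`` is the real-valued number of clusters required;
    ``clusters_per_sequence`` the integer allocation after rounding up, with
    ``power`` and ``var_theta_hat`` recomputed at that allocation so the
    rounding cost is visible.
    """

    r: float
    design_effect: float
    n_individual: float
    clusters_parallel: float
    clusters_longitudinal: float
    clusters_per_sequence: int
    var_theta_hat: float
    power: float


def compute_r(vc: BlockExchangeableComponents, m: int, chi: float) -> float:
    """Correlation r between two cluster-period means of the same cluster
    under the block-exchangeable model with constant churn chi:

        r = [m*rho*pi + (1-rho)*tau*(1-chi)] / [1 + (m-1)*rho]

    chi = 0 gives the closed-cohort value, chi = 1 the cross-sectional
    (one measurement per participant) value.
    """
    if not 0 <= chi <= 1:
        raise ValueError(f"chi must be in [0, 1], got {chi}")
    return (m * vc.rho * vc.pi + (1.0 - vc.rho) * vc.tau * (1.0 - chi)) / (
        1.0 + (m - 1) * vc.rho
    )


def design_effect(Xc: np.ndarray, r: float) -> float:
    """Longitudinal design effect DE(r) for a cluster-by-period binary
    treatment matrix with one row per cluster.

        DE(r) = K^2 (1-r)[1 + (T-1)r] /
                (4 {[K X.. - sum_t X.t^2]
                    + [X..^2 + K(T-1)X.. - (T-1) sum_t X.t^2
                       - K sum_k Xk.^2] r})

    DE(r) is invariant under replicating clusters within sequences, so it may
    be evaluated on the schematic or on the expanded matrix.
    """
    Xc = np.asarray(Xc)
    if not 0 <= r < 1:
        raise ValueError(f"r must be in [0, 1), got {r}")
    K, T = Xc.shape
    tot = design_totals(Xc)
    U = tot.grand
    W = int((tot.per_period.astype(np.int64) ** 2).sum())
    Vk = int((tot.per_cluster.astype(np.int64) ** 2).sum())
    denom = (K * U - W) + (U * U + K * (T - 1) * U - (T - 1) * W - K * Vk) * r
    if denom <= 0:
        raise SingularDesignError(
            "design has no treatment contrast at this r; design effect undefined"
        )
    return K * K * (1.0 - r) * (1.0 + (T - 1) * r) / (4.0 * denom)


def individually_randomized_n(q: PowerQuery, sigma2: float,
                              target_power: float | None = None) -> float:
    """Total sample size of an individually randomized two-arm trial:
    n_i = 4 sigma^2 (z_{1-alpha/2} + z_{1-beta})^2 / theta*^2."""
    power = target_power if target_power is not None else q.target_power
    if power is None:
        raise ValueError("target power required for a sample-size calculation")
    if q.theta == 0:
        raise ValueError("effect size must be nonzero")
    z = stats.norm.ppf(1.0 - q.alpha / 2.0) + stats.norm.ppf(power)
    return 4.0 * sigma2 * z * z / (q.theta * q.theta)


def _inv_checked(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(V, V.T):
        raise ValueError("covariance must be symmetric")
    if np.linalg.cond(V) > _COND_LIMIT:
        raise SingularCovarianceError(
            "covariance matrix of cluster-period means is numerically singular"
        )
    return np.linalg.inv(V)


def gls_variance(design: TrialDesign, V: np.ndarray) -> float:
    """Variance of the GLS estimator of the treatment effect.

    The model for the T-vector of a cluster's period means has fixed
    categorical period effects, the treatment term theta*X_k, and known
    covariance V (common to all clusters).  Then

        var(theta_hat) = [ sum_k X_k' V^-1 X_k
                           - (sum_k X_k' V^-1) (K V^-1)^-1 (sum_k V^-1 X_k) ]^-1.
    """
    Xc = expand_to_clusters(design).astype(float)
    K, T = Xc.shape
    if V.shape != (T, T):
        raise ValueError(f"covariance must be {T}x{T}, got {V.shape}")
    Vi = _inv_checked(V)
    quad = float(np.einsum("kt,ts,ks->", Xc, Vi, Xc))
    s = Xc.sum(axis=0)
    info = quad - float(s @ Vi @ s) / K
    if info <= 1e-12 * max(1.0, quad):
        raise SingularDesignError("design carries no information about the treatment effect")
    return 1.0 / info


def _power_from_variance(theta: float, alpha: float, var: float) -> float:
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(theta) / math.sqrt(var) - z_a))


def gls_power(design: TrialDesign, V: np.ndarray, q: PowerQuery) -> float:
    """Power of the two-sided level-alpha Wald test via the GLS variance."""
    return _power_from_variance(q.theta, q.alpha, gls_variance(design, V))


def power_from_design_effect(design: TrialDesign,
                             vc: BlockExchangeableComponents,
                             chi: float, q: PowerQuery) -> float:
    """Power via the design-effect route (constant churn chi).

    The implied variance of the treatment-effect estimator for the full
    design with K clusters is 4 sigma^2 DE(r) [1 + (m-1)rho] / (m K).
    """
    Xc = expand_to_clusters(design)
    r = compute_r(vc, design.m, chi)
    DE = design_effect(Xc, r)
    m, K = design.m, design.n_clusters
    var = 4.0 * vc.sigma2 * DE * (1.0 + (m - 1) * vc.rho) / (m * K)
    return _power_from_variance(q.theta, q.alpha, var)


def clusters_required(design: TrialDesign, vc: BlockExchangeableComponents,
                      chi: float, q: PowerQuery) -> PowerResult:
    """Number of clusters needed to reach the target power, by the unified
    design effect:

        K_L = DE(r) * [1 + (m-1)*rho] * n_i / m,

    rounded up to an integer number of clusters per sequence.  Achieved power
    and variance are recomputed at the integer allocation through the GLS
    route (which agrees with the design-effect route for constant churn).
    """
    m, S = design.m, design.n_sequences
    Xc = expand_to_clusters(design)
    r = compute_r(vc, m, chi)
    DE = design_effect(Xc, r)
    n_i = individually_randomized_n(q, vc.sigma2)
    K_P = (1.0 + (m - 1) * vc.rho) * n_i / m
    K_L = DE * K_P
    c = max(1, math.ceil(K_L / S - 1e-9))
    final = design.with_clusters_per_sequence((c,) * S)
    V = cov_matrix_block_exchangeable(vc, ConstantChurn(chi), m, design.n_periods)
    var = gls_variance(final, V)
    return PowerResult(
        r=r,
        design_effect=DE,
        n_individual=n_i,
        clusters_parallel=K_P,
        clusters_longitudinal=K_L,
        clusters_per_sequence=c,
        var_theta_hat=var,
        power=_power_from_variance(q.theta, q.alpha, var),
    )


def power_curve(design: TrialDesign, vc, q: PowerQuery,
                family: str = "core_group", grid=None) -> pd.DataFrame:
    """Power across a family of sampling schemes, via the GLS route.

    ``family='core_group'``: grid of expected core-group proportions g in
    [0, 1] (churn chi = 1 - g); default grid 0, 0.1, ..., 1.
    ``family='in_for_p'``: grid of rotation lengths p; default 1..T.
    The covariance model follows the type of ``vc`` (block-exchangeable or
    discrete-time decay).
    """
    T = design.n_periods
    rows = []
    if family == "core_group":
        if grid is None:
            grid = np.linspace(0.0, 1.0, 11)
        for g in grid:
            scheme = ConstantChurn(1.0 - float(g))
            V = cov_matrix(vc, scheme, design.m, T)
            rows.append({"core_group_proportion": float(g),
                         "power": gls_power(design, V, q)})
        return pd.DataFrame(rows)
    if family == "in_for_p":
        if grid is None:
            grid = range(1, T + 1)
        for p in grid:
            scheme = InForP(int(p))
            V = cov_matrix(vc, scheme, design.m, T)
            rows.append({"p": int(p), "power": gls_power(design, V, q)})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scheme family {family!r}")
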