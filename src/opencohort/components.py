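"""Variance-component parameterizations.

Two parameterizations are supported:

* block-exchangeable: a four-component decomposition of the total outcome
  variance sigma^2 into cluster, cluster-period, participant and error
  variance, expressed through the intracluster correlation rho, the cluster
  autocorrelation pi and the participant autocorrelation tau;
* discrete-time decay: a two-component decomposition (cluster-period and
  participant-level error) in which both between-period correlations decay
  geometrically with the lag, at per-period rates pi_d (cluster) and tau_d
  (participant).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidSchemeError

__all__ = ["BlockExchangeableComponents", "DecayComponents"]


def _check_unit(name: str, value: float, *, open_right: bool = False) -> float:
    value = float(value)
    hi_ok = value < 1 if open_right else value <= 1
    if not (0 <= value and hi_ok):
        hi = "1)" if open_right else "1]"
        raise InvalidSchemeError(f"{name} must be in [0, {hi}, got {value}")
    return value


@dataclass(frozen=True)
class BlockExchangeableComponents:
    """Block-exchangeable variance components (sigma^2, rho, pi, tau).

    The derived components are

    * ``sigma2_c   = sigma2 * rho * pi``            (cluster)
    * ``sigma2_cp  = sigma2 * rho * (1 - pi)``      (cluster-period)
    * ``sigma2_eta = sigma2 * (1 - rho) * tau``     (participant)
    * ``sigma2_eps = sigma2 * (1 - rho) * (1 - tau)`` (residual)

    which are nonnegative and sum to ``sigma2``.  rho is the correlation
    between two participants in the same cluster and period; pi the
    correlation between two population means of the same cluster in different
    periods; tau the correlation between two measurements on the same
    participant in different periods.
    """

    sigma2: float
    rho: float
    pi: float = 1.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not float(self.sigma2) > 0:
            raise InvalidSchemeError(f"sigma2 must be > 0, got {self.sigma2}")
        object.__setattr__(self, "sigma2", float(self.sigma2))
        object.__setattr__(self, "rho", _check_unit("rho", self.rho, open_right=True))
        object.__setattr__(self, "pi", _check_unit("pi", self.pi))
        object.__setattr__(self, "tau", _check_unit("tau", self.tau))

    @property
    def sigma2_c(self) -> float:
        return self.sigma2 * self.rho * self.pi

    @property
    def sigma2_cp(self) -> float:
        return self.sigma2 * self.rho * (1.0 - self.pi)

    @property
    def sigma2_eta(self) -> float:
        return self.sigma2 * (1.0 - self.rho) * self.tau

    @property
    def sigma2_eps(self) -> float:
        return self.sigma2 * (1.0 - self.rho) * (1.0 - self.tau)


@dataclass(frozen=True)
class DecayComponents:
    """Discrete-time decay variance components (sigma^2, rho, pi_d, tau_d).

    ``sigma2_cp = sigma2 * rho`` is the cluster-period random-effect variance
    and ``sigma2_eps = sigma2 * (1 - rho)`` the participant-level error
    variance.  Correlation between cluster-period effects d periods apart is
    pi_d**d; between a participant's errors d periods apart, tau_d**d.
    """

    sigma2: float
    rho: float
    pi_d: float = 1.0
    tau_d: float = 0.0

    def __post_init__(self) -> None:
        if not float(self.sigma2) > 0:
            raise InvalidSchemeError(f"sigma2 must be > 0, got {self.sigma2}")
        object.__setattr__(self, "sigma2", float(self.sigma2))
        object.__setattr__(self, "rho", _check_unit("rho", self.rho, open_right=True))
        object.__setattr__(self, "pi_d", _check_unit("pi_d", self.pi_d))
        object.__setattr__(self, "tau_d", _check_unit("tau_d", self.tau_d))

    @property
    def sigma2_cp(self) -> float:
        return self.sigma2 * self.rho

    @property
    def sigma2_eps(self) -> float:
        return self.sigma2 * (1.0 - self.rho)
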