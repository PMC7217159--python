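"""Open-cohort sampling schemes and realized membership structures.

A sampling scheme determines, for every pair of distinct periods (t, s), the
(expected) churn rate chi(t, s): the proportion of a cluster's period-t
participants who are absent in period s.  Retention is 1 - chi(t, s) and the
realized overlap count is n(t, s) = m * (1 - chi(t, s)).

Schemes provided:

* ``ConstantChurn`` — a fixed core group present in every period, topped up
  with fresh single-measurement participants; chi is constant over pairs.
* ``ClosedPopulation`` — independent simple random samples of size m drawn
  each period from a closed pool of M members; E[chi] = 1 - m/M.
* ``BetaChurn`` — cluster-specific churn drawn once per cluster from a
  Beta(alpha, beta) distribution with alpha + beta = m; only E[chi] =
  alpha/(alpha+beta) enters analytic calculations.
* ``InForP`` — rotating panel in which each participant is measured in at
  most p consecutive periods and 1/p of the sample is replaced each period;
  chi(t, s) = min(|t-s|/p, 1).
* ``CustomChurn`` — an arbitrary symmetric per-pair churn table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidSchemeError, MembershipConstructionError

__all__ = [
    "ConstantChurn",
    "ClosedPopulation",
    "BetaChurn",
    "InForP",
    "CustomChurn",
    "expected_churn",
    "MembershipMatrix",
    "realize_membership",
    "realize_panels",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _check_pair(t: int, s: int) -> None:
    if t == s:
        raise InvalidSchemeError(
            "churn is defined for distinct periods only (diagonal churn is 0)"
        )


@dataclass(frozen=True)
class ConstantChurn:
    """Core-group scheme: churn chi constant across all period pairs."""

    chi: float
    kind = "constant_churn"

    def __post_init__(self) -> None:
        if not 0 <= float(self.chi) <= 1:
            raise InvalidSchemeError(f"chi must be in [0, 1], got {self.chi}")
        object.__setattr__(self, "chi", float(self.chi))

    def expected_churn(self, t: int, s: int, m: int) -> float:
        _check_pair(t, s)
        return self.chi


@dataclass(frozen=True)
class ClosedPopulation:
    """Repeated simple random sampling of m participants from a closed
    population of M; expected churn 1 - m/M for every pair of periods."""

    M: int
    kind = "closed_population"

    def __post_init__(self) -> None:
        if int(self.M) < 1:
            raise InvalidSchemeError("population size M must be >= 1")
        object.__setattr__(self, "M", int(self.M))

    def _check_m(self, m: int) -> None:
        if self.M < m:
            raise InvalidSchemeError(
                f"population size M={self.M} must be >= cluster-period size m={m}"
            )

    def expected_churn(self, t: int, s: int, m: int) -> float:
        _check_pair(t, s)
        self._check_m(m)
        return 1.0 - m / self.M


@dataclass(frozen=True)
class BetaChurn:
    """Cluster-level churn drawn from Beta(alpha, beta), alpha + beta = m.

    alpha is the expected number of participants lost from one period to the
    next and beta the expected number retained, so only the mean
    alpha/(alpha+beta) matters for covariances.
    """

    alpha: float
    beta: float
    kind = "beta_churn"

    def __post_init__(self) -> None:
        if not (float(self.alpha) > 0 and float(self.beta) > 0):
            raise InvalidSchemeError("Beta parameters must be positive")
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "beta", float(self.beta))

    def _check_m(self, m: int) -> None:
        if not math.isclose(self.alpha + self.beta, m):
            raise InvalidSchemeError(
                f"Beta churn requires alpha + beta = m, got "
                f"{self.alpha} + {self.beta} != {m}"
            )

    def expected_churn(self, t: int, s: int, m: int) -> float:
        _check_pair(t, s)
        self._check_m(m)
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class InForP:
    """Rotation ("in-for-p") sampling: each participant is measured in at most
    p consecutive periods, with 1/p of the sample replaced each period."""

    p: int
    kind = "in_for_p"

    def __post_init__(self) -> None:
        if int(self.p) < 1:
            raise InvalidSchemeError("rotation length p must be >= 1")
        object.__setattr__(self, "p", int(self.p))

    def expected_churn(self, t: int, s: int, m: int) -> float:
        _check_pair(t, s)
        return min(abs(t - s) / self.p, 1.0)


@dataclass(frozen=True)
class CustomChurn:
    """User-specified symmetric per-pair churn table chi(t, s), 1-based."""

    table: np.ndarray
    kind = "custom"

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=float)
        if tab.ndim != 2 or tab.shape[0] != tab.shape[1]:
            raise InvalidSchemeError("churn table must be square")
        if not np.allclose(tab, tab.T):
            raise InvalidSchemeError("churn table must be symmetric")
        if not np.allclose(np.diag(tab), 0.0):
            raise InvalidSchemeError("diagonal churn must be 0")
        if tab.min() < 0 or tab.max() > 1:
            raise InvalidSchemeError("churn entries must lie in [0, 1]")
        tab.setflags(write=False)
        object.__setattr__(self, "table", tab)

    def expected_churn(self, t: int, s: int, m: int) -> float:
        _check_pair(t, s)
        T = self.table.shape[0]
        if not (1 <= t <= T and 1 <= s <= T):
            raise InvalidSchemeError(f"period pair ({t}, {s}) outside table of size {T}")
        return float(self.table[t - 1, s - 1])


def expected_churn(scheme, t: int, s: int, m: int) -> float:
    """Expected churn chi(t, s) between 1-based periods t != s under a scheme."""
    return scheme.expected_churn(t, s, m)


@dataclass(frozen=True)
class MembershipMatrix:
    """Realized overlap counts n(t, s) for one cluster.

    n(t, s) is the number of participants measured in both periods t and s;
    n(t, t) = m.  Any realizable membership satisfies, for every triple of
    periods (t, u, s), the inequality n(t, u) + n(u, s) <= n(t, s) + m.
    """

    n: np.ndarray
    m: int

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=np.int64)
        n.setflags(write=False)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "m", int(self.m))
        self.validate()

    def validate(self) -> None:
        n, m = self.n, self.m
        if n.ndim != 2 or n.shape[0] != n.shape[1]:
            raise MembershipConstructionError("overlap matrix must be square")
        if (n < 0).any() or (n > m).any():
            raise MembershipConstructionError("overlap counts must lie in [0, m]")
        if not (np.diag(n) == m).all():
            raise MembershipConstructionError("diagonal overlaps must equal m")
        if not (n == n.T).all():
            raise MembershipConstructionError("overlap matrix must be symmetric")
        # triple inequality n(t,u) + n(u,s) <= n(t,s) + m, all (t,u,s) at once
        lhs = n[:, :, None] + n.T[None, :, :]
        rhs = n[:, None, :] + m
        if (lhs > rhs).any():
            raise MembershipConstructionError(
                "overlap counts violate the triple inequality "
                "n(t,u) + n(u,s) <= n(t,s) + m"
            )

    @property
    def n_periods(self) -> int:
        return self.n.shape[0]

    def churn(self) -> np.ndarray:
        """Realized churn table 1 - n(t, s)/m."""
        return 1.0 - self.n / self.m

    @classmethod
    def from_panels(cls, panels: list[np.ndarray], m: int) -> "MembershipMatrix":
        """Overlap counts from per-period participant id arrays."""
        T = len(panels)
        sets = [set(map(int, ids)) for ids in panels]
        n = np.empty((T, T), dtype=np.int64)
        for t in range(T):
            for s in range(t, T):
                n[t, s] = n[s, t] = len(sets[t] & sets[s])
        return cls(n, m)

    def to_csv(self, path) -> None:
        T = self.n_periods
        cols = [f"period_{t}" for t in range(1, T + 1)]
        pd.DataFrame(self.n, columns=cols, index=cols).to_csv(path)

    @classmethod
    def from_csv(cls, path, m: int | None = None) -> "MembershipMatrix":
        df = pd.read_csv(path, index_col=0)
        n = df.to_numpy(dtype=np.int64)
        if m is None:
            m = int(n[0, 0])
        return cls(n, m)


def _core_group_panels(m: int, T: int, chi: float, start_id: int = 0):
    """Fixed core of round(m(1-chi)) participants, all periods; the rest of
    each period's slots are fresh single-measurement participants."""
    core = _round_half_up(m * (1.0 - chi))
    panels = []
    next_id = start_id + core
    core_ids = np.arange(start_id, start_id + core)
    for _ in range(T):
        fresh = np.arange(next_id, next_id + (m - core))
        next_id += m - core
        panels.append(np.concatenate([core_ids, fresh]))
    return panels


def _in_for_p_panels(m: int, T: int, p: int):
    """Rotating panel: at period 1 there are p groups with residual tenures
    1..p; each period the expiring group is replaced by a fresh group of the
    same size that stays for (up to) p periods.

    Group sizes are floor(m/p) or ceil(m/p); when m is not divisible by p the
    extra slots go to the longest-tenure starting groups (largest remainders
    first, deterministic).
    """
    base, rem = divmod(m, p)
    # groups as (ids, first_period, last_period); periods 1-based
    groups = []
    next_id = 0
    for j in range(1, p + 1):  # starting group j leaves after period j
        size = base + (1 if j > p - rem else 0)
        if size == 0:
            continue
        groups.append((np.arange(next_id, next_id + size), 1, j))
        next_id += size
    for t in range(2, T + 1):
        # replace the group whose tenure expired after period t-1
        expired = [g for g in groups if g[2] == t - 1]
        for ids, _, _ in expired:
            size = len(ids)
            groups.append((np.arange(next_id, next_id + size), t, t + p - 1))
            next_id += size
    panels = []
    for t in range(1, T + 1):
        ids = [g[0] for g in groups if g[1] <= t <= g[2]]
        panels.append(np.concatenate(ids) if ids else np.empty(0, dtype=int))
    return panels


def realize_panels(scheme, m: int, T: int, rng: np.random.Generator):
    """Draw one cluster's per-period participant id arrays under a scheme.

    Participant ids are integers unique within the cluster; a participant's
    id is stable across the periods in which they appear.
    """
    if isinstance(scheme, ConstantChurn):
        return _core_group_panels(m, T, scheme.chi)
    if isinstance(scheme, BetaChurn):
        scheme._check_m(m)
        chi_k = rng.beta(scheme.alpha, scheme.beta)
        return _core_group_panels(m, T, chi_k)
    if isinstance(scheme, ClosedPopulation):
        scheme._check_m(m)
        return [rng.choice(scheme.M, size=m, replace=False) for _ in range(T)]
    if isinstance(scheme, InForP):
        return _in_for_p_panels(m, T, scheme.p)
    raise InvalidSchemeError(
        f"no participant-level construction is defined for scheme kind "
        f"{getattr(scheme, 'kind', type(scheme).__name__)!r}"
    )


def realize_membership(scheme, m: int, T: int, rng=None) -> MembershipMatrix:
    """Realize an integer overlap matrix n(t, s) for one cluster.

    For the named schemes the matrix is built from an explicit participant
    panel construction and is always valid.  For a custom churn table, counts
    are rounded (half up) from m * (1 - chi(t, s)); if the rounded counts
    violate the triple inequality a :class:`MembershipConstructionError` is
    raised — no repair is attempted.
    """
    rng = np.random.default_rng(rng)
    if isinstance(scheme, CustomChurn):
        if scheme.table.shape[0] != T:
            raise InvalidSchemeError(
                f"churn table is {scheme.table.shape[0]}x{scheme.table.shape[0]}, "
                f"need {T}x{T}"
            )
        n = np.empty((T, T), dtype=np.int64)
        for t in range(T):
            n[t, t] = m
            for s in range(t + 1, T):
                n[t, s] = n[s, t] = _round_half_up(m * (1.0 - scheme.table[t, s]))
        return MembershipMatrix(n, m)
    panels = realize_panels(scheme, m, T, rng)
    return MembershipMatrix.from_panels(panels, m)
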