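"""Conversion of no-decay autocorrelations to decay-model parameters.

Autocorrelations (the cluster autocorrelation pi, or the participant
autocorrelation tau) estimated under a model that assumes a constant
between-period correlation absorb any decay that was actually present in the
data.  They therefore cannot be substituted directly into a discrete-time
decay model: the constant value is a lag-averaged summary, and the matching
decay parameter must be larger at lag one.

Moment matching equates the sum of all T^2 pairwise correlations under the
two models: find x in [0, 1] with

    sum_t sum_s x^|t-s| = value * T*(T-1) + T,

equivalently (grouping the double sum by lag d = |t-s|)

    T + 2 * sum_{d=1}^{T-1} (T-d) x^d = value * T*(T-1) + T.

The left side is continuous and strictly increasing from T (x=0) to T^2
(x=1) and the right side lies in [T, T^2], so the root exists and is unique.
"""

from __future__ import annotations

from scipy.optimize import brentq

__all__ = [
    "lag_weighted_sum",
    "adjust_autocorrelation",
    "implied_flat_autocorrelation",
]


def lag_weighted_sum(T: int, x: float) -> float:
    """sum_t sum_s x^|t-s| over a T x T grid, grouped by lag:
    T + 2 * sum_{d=1}^{T-1} (T-d) x^d."""
    return T + 2.0 * sum((T - d) * x ** d for d in range(1, T))


def _validate(T: int, value: float) -> None:
    if int(T) < 2:
        raise ValueError(f"need at least two periods, got T={T}")
    if not 0 <= value <= 1:
        raise ValueError(f"autocorrelation must be in [0, 1], got {value}")


def adjust_autocorrelation(T: int, value: float) -> float:
    """Decay-model autocorrelation (per-period decay rate) compatible with a
    no-decay estimate ``value`` over ``T`` periods.

    Solves the moment-matching equation by bracketing root search on [0, 1]
    to absolute tolerance 1e-10 (0 and 1 are exact fixed points).
    """
    T = int(T)
    _validate(T, value)
    if value in (0.0, 1.0):
        return float(value)
    target = value * T * (T - 1) + T
    return float(brentq(lambda x: lag_weighted_sum(T, x) - target,
                        0.0, 1.0, xtol=1e-12))


def implied_flat_autocorrelation(T: int, decayed: float) -> float:
    """Inverse conversion: the constant (no-decay) autocorrelation whose
    pairwise-correlation total matches a decay rate ``decayed``; round-trips
    with :func:`adjust_autocorrelation`."""
    T = int(T)
    _validate(T, decayed)
    return (lag_weighted_sum(T, decayed) - T) / (T * (T - 1))
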