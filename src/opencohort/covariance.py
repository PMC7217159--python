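"""Covariance matrices of cluster-period means.

Collapsing a cluster's outcomes to period means gives a T-vector whose
covariance matrix carries all the design information about the treatment
effect.  The diagonal does not depend on the sampling scheme; every
off-diagonal entry is attenuated by the (expected) churn between the two
periods, because only participants present in both periods contribute
participant-level covariance.
"""

from __future__ import annotations

import numpy as np

from .components import BlockExchangeableComponents, DecayComponents
from .exceptions import InvalidSchemeError
from .schemes import CustomChurn

__all__ = ["cov_matrix_block_exchangeable", "cov_matrix_decay", "cov_matrix"]

_PSD_TOL = -1e-10


def _check_psd(V: np.ndarray, scheme) -> np.ndarray:
    lam_min = float(np.linalg.eigvalsh(V)[0])
    if lam_min < _PSD_TOL * max(1.0, float(np.abs(V).max())):
        raise InvalidSchemeError(
            f"churn scheme implies a non-positive-semidefinite covariance "
            f"(min eigenvalue {lam_min:.3g}); "
            + ("check the custom churn table" if isinstance(scheme, CustomChurn)
               else "this should not happen for a named scheme")
        )
    return V


def cov_matrix_block_exchangeable(vc: BlockExchangeableComponents, scheme,
                                  m: int, T: int) -> np.ndarray:
    """T x T covariance of cluster-period means under the block-exchangeable
    model.

    Diagonal: sigma2_c + sigma2_cp + (sigma2_eta + sigma2_eps)/m.
    Off-diagonal (t, s): sigma2_c + sigma2_eta * (1 - chi(t, s)) / m,
    with chi the scheme's expected churn.
    """
    diag = vc.sigma2_c + vc.sigma2_cp + (vc.sigma2_eta + vc.sigma2_eps) / m
    V = np.empty((T, T))
    np.fill_diagonal(V, diag)
    for t in range(T):
        for s in range(t + 1, T):
            chi = scheme.expected_churn(t + 1, s + 1, m)
            V[t, s] = V[s, t] = vc.sigma2_c + vc.sigma2_eta * (1.0 - chi) / m
    return _check_psd(V, scheme)


def cov_matrix_decay(vc: DecayComponents, scheme, m: int, T: int) -> np.ndarray:
    """T x T covariance of cluster-period means under the discrete-time decay
    model with autoregressive participant-level errors.

    Diagonal: sigma2_cp + sigma2_eps/m.
    Off-diagonal (t, s): sigma2_cp * pi_d**|t-s|
    + (sigma2_eps/m) * tau_d**|t-s| * (1 - chi(t, s)).
    """
    diag = vc.sigma2_cp + vc.sigma2_eps / m
    V = np.empty((T, T))
    np.fill_diagonal(V, diag)
    for t in range(T):
        for s in range(t + 1, T):
            d = s - t
            chi = scheme.expected_churn(t + 1, s + 1, m)
            V[t, s] = V[s, t] = (
                vc.sigma2_cp * vc.pi_d ** d
                + vc.sigma2_eps / m * vc.tau_d ** d * (1.0 - chi)
            )
    return _check_psd(V, scheme)


def cov_matrix(vc, scheme, m: int, T: int) -> np.ndarray:
    """Dispatch on the variance-component parameterization."""
    if isinstance(vc, BlockExchangeableComponents):
        return cov_matrix_block_exchangeable(vc, scheme, m, T)
    if isinstance(vc, DecayComponents):
        return cov_matrix_decay(vc, scheme, m, T)
    raise TypeError(f"unsupported variance components {type(vc).__name__}")
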