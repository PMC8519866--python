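"""Independent reference implementations used as test oracles.

These deliberately use naive algorithms (path enumeration, direct matrix
formulas, grid search) and stay independent of the package's optimised
code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


def enumerate_origin_posteriors(
    pi: np.ndarray,
    stay: np.ndarray,
    emissions: np.ndarray,
) -> np.ndarray:
    """Posterior origin probabilities by brute-force path enumeration.

    ``pi``: (S,) initial distribution; ``stay``: (m-1,) stay probabilities
    between consecutive markers; ``emissions``: (m, S) per-marker emission
    likelihoods. Transition kernel: stay*I + (1-stay) * 1 pi'.
    """
    m, S = emissions.shape
    post = np.zeros((m, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=m):
        p = pi[path[0]] * emissions[0, path[0]]
        for t in range(1, m):
            s = stay[t - 1]
            trans = s * (path[t] == path[t - 1]) + (1 - s) * pi[path[t]]
            p *= trans * emissions[t, path[t]]
        total += p
        for t in range(m):
            post[t, path[t]] += p
    return post / total


def naive_reml_loglik(
    y: np.ndarray, X: np.ndarray, structures: list[np.ndarray], theta: np.ndarray
) -> float:
    """REML log-likelihood from the direct matrix formulas.

    ``structures`` are full (N, N) covariance structures; V = sum theta_i G_i.
    """
    n, r = X.shape
    V = sum(th * G for th, G in zip(theta, structures))
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtViX) @ X.T @ Vinv
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtViX)
    return float(
        -0.5 * ((n - r) * LOG2PI + logdet_v + logdet_x + y @ P @ y)
    )


def grid_search_reml(
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
    grids: list[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Exhaustive grid maximisation of the naive REML log-likelihood."""
    best_theta, best_ll = None, -np.inf
    for combo in itertools.product(*grids):
        ll = naive_reml_loglik(y, X, structures, np.array(combo))
        if ll > best_ll:
            best_theta, best_ll = np.array(combo), ll
    return best_theta, best_ll
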