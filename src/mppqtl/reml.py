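"""Residual maximum likelihood (REML) for variance-component mixed models.

Models have the form

    y = X beta + sum_i u_i + eps,   u_i ~ N(0, theta_i * G_i),

where each covariance structure G_i is given either as a low-rank factor
(G = F F', e.g. a QTL predictor matrix), a full Gram matrix (e.g. kinship),
or a fixed diagonal (e.g. eigenvalues after rotation). The residual is
homogeneous or grouped (family-specific variances).

The REML log-likelihood

    l(theta) = -1/2 [ (n - r) log 2 pi + log|V| + log|X' V^-1 X| + y' P y ]

is maximised by average-information (AI) REML — Newton-type updates using
the average of observed and expected information, with step halving and
box constraints — falling back to bound-constrained quasi-Newton on
log-variances when AI stalls; multi-start guards against local optima.
Two evaluation back-ends are used: a dense Cholesky path for arbitrary
structures and a Woodbury path (diagonal base plus low-rank update) that is
much faster when no full-rank Gram term is present.

Variances whose estimate lands on the boundary are snapped to exactly zero
when that does not reduce the likelihood, so the likelihood-ratio statistic
for a variance component has a well-defined point mass at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "RandomTerm",
    "FitResult",
    "TestResult",
    "fit_reml",
    "lrt_variance_component",
    "wald_test_fixed",
    "bic",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_BAD = -1.0e30  # likelihood sentinel for infeasible parameter points


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: exactly one of factor / gram / diag describes it."""

    name: str
    factor: np.ndarray | None = None  # (N, k): covariance F F'
    gram: np.ndarray | None = None  # (N, N) covariance structure
    diag: np.ndarray | None = None  # (N,) nonnegative diagonal structure

    def __post_init__(self) -> None:
        given = sum(x is not None for x in (self.factor, self.gram, self.diag))
        if given != 1:
            raise ValueError("give exactly one of factor, gram or diag")


@dataclass
class FitResult:
    varcomps: dict[str, float]
    beta: np.ndarray
    beta_cov: np.ndarray
    loglik: float
    blups: dict[str, np.ndarray]
    converged: bool
    n_iter: int
    n_obs: int
    r_fixed: int
    y_checksum: float

    def theta(self) -> np.ndarray:
        return np.array(list(self.varcomps.values()))


@dataclass
class TestResult:
    statistic: float
    p_value: float

    @property
    def minus_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


# ---------------------------------------------------------------------------
# likelihood engines
# ---------------------------------------------------------------------------


class _DenseEngine:
    """Cholesky-based evaluation; handles any mix of component structures."""

    def __init__(self, y, X, comps):
        self.y, self.X = y, X
        self.n, self.r = X.shape
        self.comps = []
        for name, kind, payload in comps:
            if kind == "factor":
                self.comps.append((name, "factor", payload, payload @ payload.T))
            else:
                self.comps.append((name, kind, payload, None))

    def value(self, theta, want_grad=True, want_ai=False):
        n, r = self.n, self.r
        V = np.zeros((n, n))
        dv = V.ravel()[:: n + 1]
        for th, (name, kind, payload, gram) in zip(theta, self.comps):
            if th == 0.0:
                continue
            if kind == "factor":
                V += th * gram
            elif kind == "gram":
                V += th * payload
            else:  # diag
                dv += th * payload
        try:
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return _BAD, np.zeros(len(theta)), None, None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        if want_grad:
            Vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
            ViX = Vinv @ self.X
            Viy = Vinv @ self.y
        else:
            ViX = linalg.cho_solve(cho, self.X, check_finite=False)
            Viy = linalg.cho_solve(cho, self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return _BAD, np.zeros(len(theta)), None, None
        XtViX_inv = np.linalg.inv(XtViX)
        XtViy = ViX.T @ self.y
        beta = XtViX_inv @ XtViy
        Py = Viy - ViX @ beta
        yPy = float(self.y @ Py)
        ll = -0.5 * ((n - r) * _LOG2PI + logdet_v + logdet_x + yPy)
        grad = np.zeros(len(theta))
        ai = None
        if want_grad:
            P = Vinv - ViX @ (XtViX_inv @ ViX.T)
            t_cols = []
            for i, (name, kind, payload, gram) in enumerate(self.comps):
                if kind == "factor":
                    PF = P @ payload
                    tr = float(np.sum(PF * payload))
                    t = payload @ (payload.T @ Py)
                elif kind == "gram":
                    tr = float(np.sum(P * payload))
                    t = payload @ Py
                else:
                    tr = float(np.diag(P) @ payload)
                    t = payload * Py
                grad[i] = -0.5 * (tr - float(t @ Py))
                t_cols.append(t)
            if want_ai:
                T = np.column_stack(t_cols)
                ai = 0.5 * (T.T @ (P @ T))
        aux = {"beta": beta, "beta_cov": XtViX_inv, "Py": Py}
        return ll, grad, aux, ai


class _LowRankEngine:
    """Woodbury evaluation for V = diag(d(theta)) + W Theta W'."""

    def __init__(self, y, X, comps):
        self.y, self.X = y, X
        self.n, self.r = X.shape
        self.blocks = []  # (comp index, column slice) into W
        self.diag_comps = []  # (comp index, vector)
        cols = []
        start = 0
        for i, (name, kind, payload) in enumerate(comps):
            if kind == "factor":
                k = payload.shape[1]
                self.blocks.append((i, slice(start, start + k)))
                cols.append(payload)
                start += k
            else:  # diag
                self.diag_comps.append((i, payload))
        self.W = np.hstack(cols) if cols else np.zeros((self.n, 0))
        self.n_comps = len(comps)

    def value(self, theta, want_grad=True, want_ai=False):
        n, r = self.n, self.r
        d = np.zeros(n)
        for i, vec in self.diag_comps:
            d += theta[i] * vec
        if np.any(d <= 0.0):
            return _BAD, np.zeros(self.n_comps), None, None
        dinv = 1.0 / d
        theta_cols = np.concatenate(
            [np.full(sl.stop - sl.start, max(theta[i], 1e-300)) for i, sl in self.blocks]
        ) if self.blocks else np.zeros(0)
        W = self.W
        K = W.shape[1]
        U = W * dinv[:, None]
        if K:
            A = W.T @ U
            C = np.diag(1.0 / theta_cols) + A
            try:
                choC = linalg.cho_factor(C, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return _BAD, np.zeros(self.n_comps), None, None
            logdet_v = (
                float(np.sum(np.log(d)))
                + float(np.sum(np.log(theta_cols)))
                + 2.0 * float(np.sum(np.log(np.diag(choC[0]))))
            )

            def vinv_mul(M):
                return dinv[..., None] * M - U @ linalg.cho_solve(
                    choC, U.T @ M, check_finite=False
                ) if M.ndim == 2 else dinv * M - U @ linalg.cho_solve(
                    choC, U.T @ M, check_finite=False
                )

        else:
            logdet_v = float(np.sum(np.log(d)))

            def vinv_mul(M):
                return dinv[..., None] * M if M.ndim == 2 else dinv * M

        Viy = vinv_mul(self.y)
        ViX = vinv_mul(self.X)
        XtViX = self.X.T @ ViX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return _BAD, np.zeros(self.n_comps), None, None
        XtViX_inv = np.linalg.inv(XtViX)
        beta = XtViX_inv @ (self.X.T @ Viy)
        Py = Viy - ViX @ beta
        yPy = float(self.y @ Py)
        ll = -0.5 * ((n - r) * _LOG2PI + logdet_v + logdet_x + yPy)
        grad = np.zeros(self.n_comps)
        ai = None
        if want_grad:
            t_cols = [None] * self.n_comps
            if K:
                ViW = vinv_mul(W)
                PW = ViW - ViX @ (XtViX_inv @ (self.X.T @ ViW))
                for i, sl in self.blocks:
                    tr = float(np.sum(PW[:, sl] * W[:, sl]))
                    q = W[:, sl].T @ Py
                    grad[i] = -0.5 * (tr - float(q @ q))
                    t_cols[i] = W[:, sl] @ q
                Cinv = linalg.cho_solve(choC, np.eye(K), check_finite=False)
                diag_vinv = dinv - np.einsum("nk,nk->n", U @ Cinv, U)
            else:
                diag_vinv = dinv
            B = ViX @ XtViX_inv
            diag_p = diag_vinv - np.einsum("nf,nf->n", B, ViX)
            py2 = Py**2
            for i, vec in self.diag_comps:
                grad[i] = -0.5 * (float(diag_p @ vec) - float(py2 @ vec))
                t_cols[i] = vec * Py
            if want_ai:
                T = np.column_stack(t_cols)
                ViT = vinv_mul(T)
                PT = ViT - ViX @ (XtViX_inv @ (self.X.T @ ViT))
                ai = 0.5 * (T.T @ PT)
        aux = {"beta": beta, "beta_cov": XtViX_inv, "Py": Py}
        return ll, grad, aux, ai


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOWRANK_MAX_COLS = 64


def _build_comps(terms, resid_groups, n):
    comps = [
        (
            t.name,
            "factor" if t.factor is not None else "gram" if t.gram is not None else "diag",
            t.factor if t.factor is not None else t.gram if t.gram is not None else t.diag,
        )
        for t in terms
    ]
    n_genetic = len(comps)
    if resid_groups is None:
        comps.append(("residual", "diag", np.ones(n)))
    else:
        labels = np.asarray(resid_groups)
        if len(labels) != n:
            raise ValueError("residual group labels do not match y")
        for g in dict.fromkeys(labels):
            comps.append((f"residual[{g}]", "diag", (labels == g).astype(float)))
    return comps, n_genetic


def _ai_reml(engine, theta0, lo, hi, maxiter=60, gtol=1e-6):
    """Average-information REML iterations with step halving and box clipping.

    Returns (theta, loglik, converged, n_iter). Convergence: an accepted
    step changes the log-likelihood by < 1e-9 (1 + |l|) and the scaled
    score theta * dl/dtheta of interior parameters is below ``gtol``
    (parameters at the boundary may keep a negative score).
    """
    theta = np.asarray(theta0, float).copy()
    ll, grad, aux, ai = engine.value(theta, want_grad=True, want_ai=True)
    if ll <= _BAD:
        return theta, ll, False, 0, aux

    n_par = len(theta)

    def kkt_satisfied(th, g, l):
        at_lo = th <= lo * (1.0 + 1e-9)
        scaled = g * np.maximum(th, lo)
        resid = np.where(at_lo, np.maximum(scaled, 0.0), np.abs(scaled))
        return float(resid.max()) < max(gtol, 1e-8 * (1.0 + abs(l)))

    for it in range(1, maxiter + 1):
        # active set: parameters pinned at the floor with an inward-pointing
        # score are frozen and removed from the Newton system
        active = (theta <= lo * (1.0 + 1e-9)) & (grad < 0.0)
        free = ~active
        delta = np.zeros(n_par)
        if free.any():
            ai_f = ai[np.ix_(free, free)]
            g_f = grad[free]
            ridge = 1e-8 * (abs(float(np.trace(ai_f))) / free.sum() + 1.0)
            try:
                delta[free] = np.linalg.solve(
                    ai_f + ridge * np.eye(free.sum()), g_f
                )
            except np.linalg.LinAlgError:
                delta[free] = g_f / (np.abs(np.diag(ai_f)) + ridge)
        step, accepted = 1.0, False
        while step >= 1.0 / 1024:
            cand = np.clip(theta + step * delta, lo, hi)
            ll2, g2, aux2, ai2 = engine.value(cand, want_grad=True, want_ai=True)
            if ll2 > _BAD and ll2 >= ll - 1e-10:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            # no uphill step found: accept the point if it satisfies the
            # boundary first-order conditions, otherwise report failure
            return theta, ll, kkt_satisfied(theta, grad, ll), it, aux
        dll = ll2 - ll
        theta, ll, grad, aux, ai = cand, ll2, g2, aux2, ai2
        if dll < 1e-9 * (1.0 + abs(ll)) and kkt_satisfied(theta, grad, ll):
            return theta, ll, True, it, aux
    return theta, ll, False, maxiter, aux


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    resid_groups: np.ndarray | None = None,
    start: dict[str, float] | None = None,
    n_starts: int = 2,
    gtol: float = 1e-6,
    maxiter: int = 300,
) -> FitResult:
    """Fit a variance-component model by REML.

    ``terms`` are the genetic random effects; the residual is homogeneous
    (``resid_groups=None``) or has one variance per group label. ``start``
    maps component names to warm-start variances (e.g. from a neighbouring
    model in a genome scan). Returns estimates, GLS fixed effects, the REML
    log-likelihood (full constant included) and BLUPs of each random term.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design matrix")

    comps, n_genetic = _build_comps(terms, resid_groups, len(y))
    names = [c[0] for c in comps]
    vary = max(float(np.var(y)), 1e-12)

    use_lowrank = all(kind in ("factor", "diag") for _, kind, _ in comps) and (
        sum(p.shape[1] for _, k, p in comps if k == "factor") <= _LOWRANK_MAX_COLS
    )
    engine_comps = [(nm, kind, payload) for nm, kind, payload in comps]
    engine = (
        _LowRankEngine(y, X, engine_comps)
        if use_lowrank
        else _DenseEngine(y, X, engine_comps)
    )

    lo = np.array(
        [vary * (1e-12 if i < n_genetic else 1e-8) for i in range(len(comps))]
    )
    hi = np.full(len(comps), vary * 1e4 + 1e-300)
    bounds = list(zip(np.log(lo), np.log(hi)))

    def objective(phi):
        th = np.exp(phi)
        ll, grad, _, _ = engine.value(th, want_grad=True)
        if ll <= _BAD:
            return -_BAD, np.zeros_like(phi)
        return -ll, -grad * th

    starts = []
    if start is not None:
        s0 = np.array([max(start.get(nm, vary / len(comps)), lo[i]) for i, nm in enumerate(names)])
        starts.append(np.minimum(s0, hi))
    eq = np.full(len(comps), vary / len(comps))
    starts.append(eq)
    resid_heavy = np.empty(len(comps))
    resid_heavy[:n_genetic] = 0.1 * vary / max(n_genetic, 1)
    resid_heavy[n_genetic:] = 0.9 * vary / (len(comps) - n_genetic)
    starts.append(resid_heavy)
    starts = starts[: (1 if start is not None else 0) + n_starts]

    best_theta, best_ll, best_conv, best_iter, best_aux = None, -np.inf, False, 0, None
    for s in starts:
        theta_s, ll_s, conv_s, it_s, aux_s = _ai_reml(
            engine, np.clip(s, lo, hi), lo, hi, gtol=gtol
        )
        if not conv_s:
            # fall back: polish with quasi-Newton on log-variances
            res = optimize.minimize(
                objective,
                np.log(np.clip(theta_s, lo, hi)),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
            )
            if -res.fun >= ll_s:
                theta_s, conv_s = np.exp(res.x), bool(res.success)
                it_s += int(res.nit)
                ll_s, _, aux_s, _ = engine.value(theta_s, want_grad=False)
        if ll_s > best_ll:
            best_theta, best_ll, best_conv, best_iter, best_aux = (
                theta_s, ll_s, conv_s, it_s, aux_s,
            )
        if start is not None and conv_s:
            break  # warm start converged; skip cold starts
    theta = best_theta
    ll_best = best_ll

    # snap boundary genetic variances to exactly zero when harmless
    snap = theta.copy()
    small = np.zeros(len(comps), dtype=bool)
    small[:n_genetic] = theta[:n_genetic] < 1e-8 * vary
    if small.any():
        probe = snap.copy()
        probe[small] = 1e-30  # numerically indistinguishable from zero
        ll_snap, _, aux_snap, _ = engine.value(probe, want_grad=False)
        if ll_snap >= ll_best - 1e-8:
            snap[small] = 0.0
            ll, aux = ll_snap, aux_snap
        else:
            small[:] = False
            ll, aux = ll_best, best_aux
    else:
        ll, aux = ll_best, best_aux

    Py = aux["Py"]
    blups = {}
    for th, t in zip(snap[:n_genetic], terms):
        if t.factor is not None:
            blups[t.name] = th * (t.factor.T @ Py)
        elif t.gram is not None:
            blups[t.name] = th * (t.gram @ Py)
        else:
            blups[t.name] = th * (t.diag * Py)
    varcomps = dict(zip(names, snap))
    return FitResult(
        varcomps=varcomps,
        beta=aux["beta"],
        beta_cov=aux["beta_cov"],
        loglik=float(ll),
        blups=blups,
        converged=bool(best_conv),
        n_iter=int(best_iter),
        n_obs=len(y),
        r_fixed=X.shape[1],
        y_checksum=float(np.sum(y) + np.sum(y**2)),
    )


# ---------------------------------------------------------------------------
# tests and information criteria
# ---------------------------------------------------------------------------


def lrt_variance_component(fit_null: FitResult, fit_alt: FitResult) -> TestResult:
    """Likelihood-ratio test of one variance component on the boundary.

    LRT = max(0, 2 (l_A - l_0)); under the null the statistic follows the
    mixture 0.5 chi2_0 + 0.5 chi2_1, so p = 0.5 P(chi2_1 >= LRT) for a
    positive statistic and p = 1 at LRT = 0.
    """
    if fit_null.n_obs != fit_alt.n_obs or not np.isclose(
        fit_null.y_checksum, fit_alt.y_checksum
    ):
        raise ValueError("null and alternative fits use different data")
    lrt = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = 1.0 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return TestResult(statistic=lrt, p_value=max(p, 1e-300))


def wald_test_fixed(fit: FitResult, coef_index: int = -1) -> TestResult:
    """Wald test of one fixed effect from a REML fit.

    The statistic beta^2 / var(beta), with the GLS variance from
    (X' V^-1 X)^-1, is referred to chi-square with 1 df.
    """
    beta = float(fit.beta[coef_index])
    var = float(fit.beta_cov[coef_index, coef_index])
    if var <= 0:
        raise ValueError("non-positive coefficient variance")
    w = beta**2 / var
    p = float(stats.chi2.sf(w, df=1))
    return TestResult(statistic=w, p_value=max(p, 1e-300))


def bic(
    df_fixed: int, df_var: int, n: int, r: int, loglik: float
) -> float:
    """Bayesian information criterion for a REML fit (lower is better):

        BIC = (DF_fixed + DF_var) * ln(n - r + DF_fixed) - 2 ln(L_max)

    with n observations, r the rank of the fixed design, DF_fixed and
    DF_var the fixed- and variance-parameter counts.
    """
    m = n - r + df_fixed
    if m <= 0:
        raise ValueError("n - r + DF_fixed must be positive")
    return float((df_fixed + df_var) * np.log(m) - 2.0 * loglik)
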