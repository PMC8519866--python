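"""Genome-wide QTL scans: thresholds, cofactor selection, iterative rescans.

The scan walks the map marker by marker, fitting the chosen mixed model
with a QTL term at the tested position against the matched null model
(same terms minus the QTL). IBD models test the QTL variance with the
boundary likelihood-ratio test; the IBS benchmark uses a Wald test of the
fixed substitution effect. The null model is refitted once per
(chromosome x cofactor configuration), not per marker.

Models with cofactors iterate: scan, pick super-threshold cofactors
greedily with an exclusion window, rescan with the cofactors in the model,
and stop when the cofactor set stabilises. When a tested marker falls
inside a cofactor's exclusion window that cofactor is dropped for that test
(composite-interval-mapping convention); a strict skip mode that performs
no test there is available instead.

For kinship models on single-family designs the scan rotates each
chromosome into the eigenbasis of its leave-one-chromosome-out kinship
matrix, which turns the polygenic covariance into a diagonal and makes
every per-marker fit a cheap diagonal-plus-low-rank problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ibd import IBDTensor
from .kinship import KinshipMatrix
from .models import (
    IBD_MODELS,
    build_spec,
    family_design_matrix,
    model_family_residual,
    model_uses_cofactors,
    model_uses_kinship,
)
from .reml import (
    FitResult,
    RandomTerm,
    TestResult,
    bic,
    fit_reml,
    lrt_variance_component,
    wald_test_fixed,
)
from .simulate import CrossingPlan

__all__ = [
    "ScanContext",
    "ScanProfile",
    "QTLReport",
    "bonferroni_threshold",
    "genome_scan",
    "select_cofactors",
    "mqm_iterate",
    "call_qtls_and_success",
    "select_model_by_bic",
]


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    """Genome-wide -log10(p) threshold: -log10(alpha / n_markers).

    An explicit threshold override elsewhere in the pipeline bypasses this
    formula.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return float(-np.log10(alpha / n_markers))


@dataclass
class ScanContext:
    """Bundles everything a scan needs for one dataset."""

    y: np.ndarray
    plan: CrossingPlan
    tensor: IBDTensor
    kinships: dict[str, KinshipMatrix] | None = None  # LOCO, keyed by chromosome
    dosages: np.ndarray | None = None  # observed (N, m) for the IBS benchmark
    _eig: dict = field(default_factory=dict, repr=False)
    _imputed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float).ravel()
        if len(self.y) != len(self.tensor.individuals):
            raise ValueError("phenotype and IBD tensor cover different individuals")
        self.family_labels = self.plan.family_labels()
        if len(self.family_labels) != len(self.y):
            raise ValueError("plan and phenotype cover different individuals")

    @property
    def gmap(self):
        return self.tensor.gmap

    def kin_eig(self, chrom: str):
        """Cached eigendecomposition of the LOCO kinship for one chromosome."""
        if chrom not in self._eig:
            k = self.kinships[chrom].values
            lam, u = np.linalg.eigh(k)
            self._eig[chrom] = (np.clip(lam, 0.0, None), u)
        return self._eig[chrom]

    def imputed_dosage(self, j: int) -> np.ndarray:
        if self._imputed is None:
            d = np.array(self.dosages, float)
            mu = np.nanmean(d, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            inds = np.where(np.isnan(d))
            d[inds] = mu[inds[1]]
            self._imputed = d
        return self._imputed[:, j]


@dataclass
class ScanProfile:
    """Per-marker test results of one genome scan."""

    table: pd.DataFrame  # marker, chrom, pos_cm, minus_log10_p, statistic,
    # tested, skip_reason, cofactors
    model: str

    def peak(self, chrom: str) -> pd.Series | None:
        sub = self.table[(self.table["chrom"] == chrom) & self.table["tested"]]
        if sub.empty or sub["minus_log10_p"].isna().all():
            return None
        return sub.loc[sub["minus_log10_p"].idxmax()]


@dataclass
class QTLReport:
    qtls: pd.DataFrame  # marker, chrom, pos_cm, minus_log10_p
    threshold: float
    cofactor_history: list[list[str]]
    stabilized: bool
    n_rounds: int


def _qtl_start(null_fit: FitResult, vary: float) -> dict[str, float]:
    start = dict(null_fit.varcomps)
    start["qtl"] = 0.05 * vary
    return start


def genome_scan(
    ctx: ScanContext,
    model_name: str,
    cofactors: tuple[str, ...] | list[str] = (),
    step: int = 1,
    exclusion_cm: float = 20.0,
    skip_in_window: bool = False,
    ibs_fast: bool = False,
    markers: list[str] | None = None,
) -> ScanProfile:
    """Scan the genome with one model and a fixed cofactor set.

    ``step`` thins the tested marker grid (every ``step``-th marker per
    chromosome); ``exclusion_cm`` is the radius of the window around a
    cofactor within which that cofactor is dropped from the model (or, with
    ``skip_in_window``, no test is performed). ``ibs_fast`` reuses the
    null-model variance components across markers for the IBS benchmark
    instead of refitting them per marker.
    """
    gmap = ctx.gmap
    half = exclusion_cm
    use_kin = model_uses_kinship(model_name)
    if use_kin and not ctx.kinships:
        raise ValueError(f"model {model_name} needs LOCO kinship matrices")
    is_ibs = model_name == "IBS.Kin"
    if is_ibs and ctx.dosages is None:
        raise ValueError("IBS.Kin needs observed marker dosages")
    single_family = ctx.plan.n_families == 1
    rotate = use_kin and single_family

    if markers is None:
        test_idx = [
            j
            for c in gmap.chromosomes
            for j in range(gmap.chrom_slice(c).start, gmap.chrom_slice(c).stop, step)
        ]
    else:
        test_idx = [gmap.marker_index(m) for m in markers]

    cof_pos = {m: (gmap.chrom_of(m), gmap.pos_of(m)) for m in cofactors}
    cof_pred = {m: ctx.tensor.predictors(m) for m in cofactors}
    X = family_design_matrix(ctx.family_labels)
    vary = max(float(np.var(ctx.y)), 1e-12)

    null_cache: dict = {}
    last_null_theta: dict[str, float] | None = None
    rows = []
    rot_cache: dict = {}

    chroms_arr = gmap.table["chrom"].to_numpy()
    pos_arr = gmap.table["pos_cm"].to_numpy()
    marker_arr = gmap.markers

    for j in test_idx:
        chrom, pos, marker = chroms_arr[j], pos_arr[j], marker_arr[j]
        in_window = [
            m
            for m, (c, p) in cof_pos.items()
            if c == chrom and abs(p - pos) <= half
        ]
        if skip_in_window and in_window and marker not in in_window:
            rows.append(
                (marker, chrom, pos, np.nan, np.nan, False, "in-cofactor-window", "")
            )
            continue
        active = tuple(m for m in cofactors if m not in in_window)
        cof_str = "|".join(active)

        if rotate:
            if chrom not in rot_cache:
                lam, u = ctx.kin_eig(chrom)
                rot_cache[chrom] = (
                    lam,
                    u,
                    u.T @ ctx.y,
                    u.T @ X,
                    {m: u.T @ cof_pred[m] for m in cofactors},
                )
            lam, u, y_r, X_r, cof_r = rot_cache[chrom]
        else:
            lam = u = None
            y_r, X_r, cof_r = ctx.y, X, cof_pred

        if is_ibs:
            xq = ctx.imputed_dosage(j)
            if np.std(xq) == 0.0:
                rows.append((marker, chrom, pos, 0.0, np.nan, False, "monomorphic", cof_str))
                continue
            xq_r = u.T @ xq if rotate else xq
            key = (chrom, None)
            if ibs_fast:
                if key not in null_cache:
                    null_cache[key] = _fit_ibs_null(ctx, chrom, X_r, y_r, lam, rotate)
                test = _wald_fast(ctx, chrom, X_r, y_r, xq_r, null_cache[key], lam, rotate)
            else:
                X_aug = np.column_stack([X_r, xq_r])
                term = (
                    [RandomTerm("polygenic", diag=lam)]
                    if rotate
                    else [RandomTerm("polygenic", gram=ctx.kinships[chrom].values)]
                )
                start = last_null_theta
                fit = fit_reml(y_r, X_aug, term, None, start=start)
                last_null_theta = dict(fit.varcomps)
                test = wald_test_fixed(fit, coef_index=-1)
            rows.append(
                (marker, chrom, pos, test.minus_log10_p, test.statistic, True, "", cof_str)
            )
            continue

        # IBD models: boundary LRT on the QTL variance
        null_key = (chrom if (use_kin or rotate) else None, active)
        if null_key not in null_cache:
            spec0 = build_spec(
                model_name,
                ctx.family_labels,
                qtl_predictors=None,
                cofactor_predictors={m: cof_r[m] for m in active},
                kinship=None if rotate or not use_kin else ctx.kinships[chrom].values,
                kinship_eigvals=lam if rotate else None,
            )
            spec0.X = X_r
            if rotate:
                spec0.resid_groups = None  # uniform stays uniform under rotation
            fit0 = fit_reml(
                y_r, spec0.X, spec0.terms, spec0.resid_groups, start=last_null_theta
            )
            null_cache[null_key] = fit0
            last_null_theta = dict(fit0.varcomps)
        fit0 = null_cache[null_key]

        mq = ctx.tensor.predictors(marker)
        mq_r = u.T @ mq if rotate else mq
        spec1 = build_spec(
            model_name,
            ctx.family_labels,
            qtl_predictors=mq_r,
            cofactor_predictors={m: cof_r[m] for m in active},
            kinship=None if rotate or not use_kin else ctx.kinships[chrom].values,
            kinship_eigvals=lam if rotate else None,
        )
        spec1.X = X_r
        if rotate:
            spec1.resid_groups = None
        fit1 = fit_reml(
            y_r, spec1.X, spec1.terms, spec1.resid_groups, start=_qtl_start(fit0, vary)
        )
        if fit1.loglik < fit0.loglik - 1e-6:
            # warm start trapped below the null: retry from cold starts
            fit1 = fit_reml(y_r, spec1.X, spec1.terms, spec1.resid_groups)
        test = lrt_variance_component(fit0, fit1)
        rows.append(
            (marker, chrom, pos, test.minus_log10_p, test.statistic, True, "", cof_str)
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "marker",
            "chrom",
            "pos_cm",
            "minus_log10_p",
            "statistic",
            "tested",
            "skip_reason",
            "cofactors",
        ],
    )
    return ScanProfile(table, model_name)


def _fit_ibs_null(ctx, chrom, X_r, y_r, lam, rotate):
    term = (
        [RandomTerm("polygenic", diag=lam)]
        if rotate
        else [RandomTerm("polygenic", gram=ctx.kinships[chrom].values)]
    )
    return fit_reml(y_r, X_r, term, None)


def _wald_fast(ctx, chrom, X_r, y_r, xq_r, null_fit, lam, rotate):
    """GLS Wald test with variance components fixed at the null estimates."""
    th_g = null_fit.varcomps["polygenic"]
    th_e = null_fit.varcomps["residual"]
    n = len(y_r)
    if rotate:
        d = th_g * lam + th_e
        vinv = 1.0 / d
        X_aug = np.column_stack([X_r, xq_r])
        XtViX = (X_aug * vinv[:, None]).T @ X_aug
        XtViy = (X_aug * vinv[:, None]).T @ y_r
    else:
        V = th_g * ctx.kinships[chrom].values + th_e * np.eye(n)
        X_aug = np.column_stack([X_r, xq_r])
        ViX = np.linalg.solve(V, X_aug)
        XtViX = X_aug.T @ ViX
        XtViy = ViX.T @ y_r
    cov = np.linalg.inv(XtViX)
    beta = cov @ XtViy
    w = float(beta[-1] ** 2 / cov[-1, -1])
    return TestResult(statistic=w, p_value=max(float(stats.chi2.sf(w, 1)), 1e-300))


def select_cofactors(
    profile: ScanProfile, threshold: float, exclusion_cm: float = 20.0
) -> list[str]:
    """Greedy peak selection above the threshold.

    Repeatedly picks the highest -log10(p) above the threshold and masks all
    markers within the exclusion radius on the same chromosome.
    """
    half = exclusion_cm
    sub = profile.table[profile.table["tested"]].dropna(subset=["minus_log10_p"])
    sub = sub.sort_values("minus_log10_p", ascending=False)
    chosen: list[tuple[str, str, float]] = []
    for _, row in sub.iterrows():
        if row["minus_log10_p"] <= threshold:
            break
        if any(
            c == row["chrom"] and abs(p - row["pos_cm"]) <= half
            for _, c, p in chosen
        ):
            continue
        chosen.append((row["marker"], row["chrom"], row["pos_cm"]))
    return [m for m, _, _ in chosen]


def _cofactor_sets_match(a: list[str], b: list[str], gmap, tol_cm: float = 5.0) -> bool:
    """Set equality up to small positional jitter.

    Rescans move a cofactor by a marker or two around the same peak; such a
    configuration is considered stabilised when both sets have the same
    per-chromosome cardinality and corresponding positions differ by at
    most ``tol_cm``.
    """
    if len(a) != len(b):
        return False
    if set(a) == set(b):
        return True
    by_chrom_a: dict[str, list[float]] = {}
    by_chrom_b: dict[str, list[float]] = {}
    for m in a:
        by_chrom_a.setdefault(gmap.chrom_of(m), []).append(gmap.pos_of(m))
    for m in b:
        by_chrom_b.setdefault(gmap.chrom_of(m), []).append(gmap.pos_of(m))
    if set(by_chrom_a) != set(by_chrom_b):
        return False
    for c in by_chrom_a:
        pa, pb = sorted(by_chrom_a[c]), sorted(by_chrom_b[c])
        if len(pa) != len(pb):
            return False
        if any(abs(x - y) > tol_cm for x, y in zip(pa, pb)):
            return False
    return True


def mqm_iterate(
    ctx: ScanContext,
    model_name: str,
    threshold: float,
    step: int = 1,
    exclusion_cm: float = 20.0,
    max_rounds: int = 10,
    skip_in_window: bool = False,
    ibs_fast: bool = False,
) -> tuple[ScanProfile, QTLReport]:
    """Iterate scans until the cofactor set (hence the profile) stabilises.

    Models without cofactor support run a single scan. QTLs are the
    super-threshold peaks of the final profile after greedy window merging.
    """
    cofactors: list[str] = []
    history: list[list[str]] = []
    stabilized = True
    profile = genome_scan(
        ctx, model_name, cofactors, step, exclusion_cm, skip_in_window, ibs_fast
    )
    n_rounds = 1
    if model_uses_cofactors(model_name):
        stabilized = False
        seen = {frozenset()}
        for _ in range(max_rounds - 1):
            new = select_cofactors(profile, threshold, exclusion_cm)
            history.append(new)
            if _cofactor_sets_match(new, cofactors, ctx.gmap):
                stabilized = True
                break
            if frozenset(new) in seen:
                # the iteration cycles between configurations; keep the
                # current profile and report non-stabilisation
                break
            seen.add(frozenset(new))
            cofactors = new
            profile = genome_scan(
                ctx, model_name, cofactors, step, exclusion_cm, skip_in_window, ibs_fast
            )
            n_rounds += 1
        else:
            stabilized = _cofactor_sets_match(
                select_cofactors(profile, threshold, exclusion_cm), cofactors, ctx.gmap
            )
    peaks = select_cofactors(profile, threshold, exclusion_cm)
    sub = profile.table.set_index("marker")
    qtls = pd.DataFrame(
        {
            "marker": peaks,
            "chrom": [sub.loc[m, "chrom"] for m in peaks],
            "pos_cm": [sub.loc[m, "pos_cm"] for m in peaks],
            "minus_log10_p": [sub.loc[m, "minus_log10_p"] for m in peaks],
        }
    )
    return profile, QTLReport(qtls, threshold, history, stabilized, n_rounds)


def call_qtls_and_success(
    profile: ScanProfile,
    truth: pd.DataFrame,
    threshold: float,
    window_cm: float = 20.0,
) -> pd.DataFrame:
    """Detection outcome per true QTL.

    A QTL counts as detected when the profile peak on its chromosome
    exceeds the threshold and lies within ``window_cm`` of the true
    position. ``truth`` needs columns marker, chrom, pos_cm.
    """
    rows = []
    for _, t in truth.iterrows():
        peak = profile.peak(str(t["chrom"]))
        if peak is None:
            rows.append(
                {
                    "marker": t["marker"],
                    "chrom": t["chrom"],
                    "true_pos_cm": t["pos_cm"],
                    "peak_marker": None,
                    "peak_pos_cm": np.nan,
                    "peak_value": np.nan,
                    "distance_cm": np.nan,
                    "success": False,
                }
            )
            continue
        dist = abs(float(peak["pos_cm"]) - float(t["pos_cm"]))
        success = bool(peak["minus_log10_p"] > threshold and dist <= window_cm)
        rows.append(
            {
                "marker": t["marker"],
                "chrom": t["chrom"],
                "true_pos_cm": float(t["pos_cm"]),
                "peak_marker": peak["marker"],
                "peak_pos_cm": float(peak["pos_cm"]),
                "peak_value": float(peak["minus_log10_p"]),
                "distance_cm": dist,
                "success": success,
            }
        )
    return pd.DataFrame(rows)


def select_model_by_bic(
    y: np.ndarray,
    family_labels: np.ndarray,
    qtl_sets: dict[str, dict[str, np.ndarray]],
    kinship: np.ndarray | None = None,
) -> tuple[str, pd.DataFrame]:
    """Pick the IBD model with the smallest BIC, each fitted with its own
    final QTL set jointly; ties break toward fewer variance parameters."""
    X = family_design_matrix(family_labels)
    r = X.shape[1]
    rows = []
    for name, qtls in qtl_sets.items():
        if name not in IBD_MODELS:
            raise ValueError(f"BIC selection covers the IBD models, not {name!r}")
        terms = [RandomTerm(f"qtl[{m}]", factor=mq) for m, mq in qtls.items()]
        if model_uses_kinship(name):
            if kinship is None:
                raise ValueError(f"model {name} needs a kinship matrix")
            terms.append(RandomTerm("polygenic", gram=kinship))
        resid = np.asarray(family_labels) if model_family_residual(name) else None
        fit = fit_reml(y, X, terms, resid)
        df_var = len(terms) + (len(dict.fromkeys(family_labels)) if resid is not None else 1)
        value = bic(r, df_var, fit.n_obs, r, fit.loglik)
        rows.append({"model": name, "bic": value, "df_var": df_var, "loglik": fit.loglik})
    table = pd.DataFrame(rows)
    best_bic = table["bic"].min()
    ties = table[np.isclose(table["bic"], best_bic, rtol=0.0, atol=1e-9)]
    best = ties.sort_values("df_var").iloc[0]["model"]
    return str(best), table
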