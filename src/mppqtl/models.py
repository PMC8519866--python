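"""The six mixed models for IBD- and IBS-based QTL mapping.

All models share the fixed part X beta, with X the N x F family-indicator
matrix (a single MAGIC family degenerates to a global intercept). They
differ in the genetic predictor (IBD parental-origin predictors versus the
observed IBS marker dosage), the genome-background correction (none,
cofactors, a kinship-structured polygenic term, or both) and the residual
structure (uniform or family-specific variances):

======================  =========  ==================  ==================
model                   predictor  background          residual
======================  =========  ==================  ==================
IBD.SQM_U               IBD        none                uniform
IBD.SQM_F               IBD        none                family-specific
IBD.MQM_F               IBD        cofactors           family-specific
IBD.Kin_F               IBD        polygenic (K)       family-specific
IBD.MQMkin_F            IBD        cofactors + K       family-specific
IBS.Kin  (benchmark)    IBS        polygenic (K)       uniform
======================  =========  ==================  ==================

IBD models treat the P parental QTL effects as a random vector
a_q ~ N(0, I_P sigma_q^2) and test sigma_q^2 = 0 with a boundary LRT; the
IBS benchmark fits a fixed bi-allelic substitution effect and uses a Wald
test. Cofactor terms enter as random effects with their own variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import FitResult, RandomTerm, fit_reml

__all__ = [
    "MODEL_NAMES",
    "IBD_MODELS",
    "ModelSpec",
    "model_uses_kinship",
    "model_uses_cofactors",
    "model_family_residual",
    "build_spec",
    "family_design_matrix",
    "estimate_parental_effects",
]

MODEL_NAMES = (
    "IBD.SQM_U",
    "IBD.SQM_F",
    "IBD.MQM_F",
    "IBD.Kin_F",
    "IBD.MQMkin_F",
    "IBS.Kin",
)
IBD_MODELS = MODEL_NAMES[:5]


def model_uses_kinship(name: str) -> bool:
    return name in ("IBD.Kin_F", "IBD.MQMkin_F", "IBS.Kin")


def model_uses_cofactors(name: str) -> bool:
    return name in ("IBD.MQM_F", "IBD.MQMkin_F")


def model_family_residual(name: str) -> bool:
    return name.endswith("_F")


def family_design_matrix(family_labels: np.ndarray) -> np.ndarray:
    """N x F indicator matrix of family membership (order of appearance)."""
    labels = np.asarray(family_labels)
    fams = list(dict.fromkeys(labels))
    return np.column_stack([(labels == f).astype(float) for f in fams])


@dataclass
class ModelSpec:
    """Assembled design for one fit: fixed part, random terms, residual."""

    name: str
    X: np.ndarray
    terms: list[RandomTerm]
    resid_groups: np.ndarray | None
    qtl_term: str | None  # name of the tested term, None for null models

    def fit(self, y: np.ndarray, start: dict[str, float] | None = None, **kw) -> FitResult:
        return fit_reml(y, self.X, self.terms, self.resid_groups, start=start, **kw)


def build_spec(
    name: str,
    family_labels: np.ndarray,
    qtl_predictors: np.ndarray | None = None,
    cofactor_predictors: dict[str, np.ndarray] | None = None,
    kinship: np.ndarray | None = None,
    marker_dosage: np.ndarray | None = None,
    kinship_eigvals: np.ndarray | None = None,
) -> ModelSpec:
    """Assemble the design of one of the six models.

    ``qtl_predictors`` is the N x P matrix of IBD predictors at the tested
    locus (omit it for the null model); ``cofactor_predictors`` maps
    cofactor marker ids to their predictor matrices. Kinship models need
    ``kinship`` (or, in a rotated coordinate system, ``kinship_eigvals``);
    IBS.Kin needs the observed ``marker_dosage`` and appends it to the fixed
    part.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    X = family_design_matrix(family_labels)
    terms: list[RandomTerm] = []
    qtl_term = None

    if name == "IBS.Kin":
        if marker_dosage is not None:
            X = np.column_stack([X, np.asarray(marker_dosage, float)])
            qtl_term = "marker"
    else:
        if qtl_predictors is not None:
            terms.append(RandomTerm("qtl", factor=np.asarray(qtl_predictors, float)))
            qtl_term = "qtl"
        if model_uses_cofactors(name):
            for marker, mc in (cofactor_predictors or {}).items():
                terms.append(
                    RandomTerm(f"cofactor[{marker}]", factor=np.asarray(mc, float))
                )
    if model_uses_kinship(name):
        if kinship_eigvals is not None:
            terms.append(RandomTerm("polygenic", diag=np.asarray(kinship_eigvals, float)))
        elif kinship is not None:
            terms.append(RandomTerm("polygenic", gram=np.asarray(kinship, float)))
        else:
            raise ValueError(f"model {name} needs a kinship matrix")

    resid = np.asarray(family_labels) if model_family_residual(name) else None
    return ModelSpec(name, X, terms, resid, qtl_term)


def estimate_parental_effects(
    y: np.ndarray,
    model_name: str,
    family_labels: np.ndarray,
    qtl_predictors: dict[str, np.ndarray],
    kinship: np.ndarray | None = None,
    founder_names: list[str] | None = None,
) -> tuple[pd.DataFrame, FitResult]:
    """BLUPs of parental effects at the final QTL candidates, fitted jointly.

    Every QTL enters the chosen model as its own random term; the returned
    frame has one row per QTL and one column per founder. BLUPs of a QTL
    whose variance lands at zero are exactly zero.
    """
    X = family_design_matrix(family_labels)
    terms = [
        RandomTerm(f"qtl[{m}]", factor=np.asarray(mq, float))
        for m, mq in qtl_predictors.items()
    ]
    if model_uses_kinship(model_name) and kinship is not None:
        terms.append(RandomTerm("polygenic", gram=np.asarray(kinship, float)))
    resid = np.asarray(family_labels) if model_family_residual(model_name) else None
    fit = fit_reml(y, X, terms, resid)
    rows = {}
    for m in qtl_predictors:
        rows[m] = fit.blups[f"qtl[{m}]"]
    n_founders = len(next(iter(qtl_predictors.values()))[0])
    if founder_names is None:
        founder_names = [f"P{j + 1}" for j in range(n_founders)]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=founder_names)
    return table, fit
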