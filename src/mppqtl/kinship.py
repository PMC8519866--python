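"""Genomic relationship matrices: VanRaden kinship and LOCO variants.

K = W W' / (2 sum_k p_k (1 - p_k)) with W the column-centered dosage matrix
(dosage - 2p per marker) and p the sample allele frequency. Missing dosages
are mean-imputed per marker before centering. For scans, leave-one-
chromosome-out (LOCO) kinship excludes the scanned chromosome to avoid
proximal contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap

__all__ = ["KinshipMatrix", "vanraden_kinship", "loco_kinship"]


@dataclass
class KinshipMatrix:
    values: np.ndarray  # (N, N) symmetric PSD
    individuals: list[str]
    markers_used: np.ndarray  # marker ids entering the computation
    excluded_chrom: str | None = None


def vanraden_kinship(
    dosages: np.ndarray,
    individuals: list[str] | None = None,
    marker_ids: np.ndarray | None = None,
    marker_subset: np.ndarray | None = None,
    ridge: float = 0.0,
) -> KinshipMatrix:
    """IBS-based genomic kinship from an (N, m) dosage matrix (NaN = missing).

    ``marker_subset`` is a boolean or index array restricting the columns
    used. An optional ``ridge`` adds eps * I to stabilise downstream REML.
    """
    d = np.asarray(dosages, dtype=float)
    if marker_subset is not None:
        d = d[:, marker_subset]
        if marker_ids is not None:
            marker_ids = np.asarray(marker_ids)[marker_subset]
    if d.ndim != 2 or d.shape[1] == 0:
        raise ValueError("need a non-empty 2-D dosage matrix")
    # mean-impute missing entries per marker
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing column
    d = np.where(np.isnan(d), col_mean, d)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: kinship denominator is zero")
    w = d - 2.0 * p
    k = (w @ w.T) / denom
    if ridge:
        k = k + ridge * np.eye(k.shape[0])
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(k.shape[0])]
    if marker_ids is None:
        marker_ids = np.arange(d.shape[1])
    return KinshipMatrix(k, list(individuals), np.asarray(marker_ids))


def loco_kinship(
    dosages: np.ndarray,
    gmap: GeneticMap,
    individuals: list[str] | None = None,
    ridge: float = 0.0,
) -> dict[str, KinshipMatrix]:
    """One kinship matrix per chromosome, built from all other chromosomes.

    When scanning a marker on chromosome c, the matrix keyed by c is used.
    Raises on single-chromosome maps, where LOCO is impossible.
    """
    chroms = gmap.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO kinship needs at least 2 chromosomes")
    chrom_per_marker = gmap.table["chrom"].to_numpy()
    out = {}
    for c in chroms:
        keep = chrom_per_marker != c
        km = vanraden_kinship(
            dosages,
            individuals=individuals,
            marker_ids=gmap.markers,
            marker_subset=keep,
            ridge=ridge,
        )
        km.excluded_chrom = c
        out[c] = km
    return out
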