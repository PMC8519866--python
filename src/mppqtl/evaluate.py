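"""Replication harness: mapping power, resolution and false positives.

Each replicate simulates a fresh population (new founder draws, meioses,
phenotypes and missingness), reconstructs IBD, builds LOCO kinship and runs
the requested models through the iterative scan. Power is the fraction of
replicates in which a major QTL is detected under the threshold-and-window
rule; resolution is the mean distance between the true position and the
chromosome peak; false positives are counted as super-threshold markers on
the QTL-free chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ibd import calibrate_junction_density, ibd_posteriors
from .kinship import loco_kinship
from .scan import ScanContext, ScanProfile, call_qtls_and_success, mqm_iterate

__all__ = [
    "ReplicationResult",
    "PerformanceSummary",
    "run_replication_study",
    "summarize_performance",
    "false_positive_count",
    "expected_false_positives",
]


@dataclass
class ReplicationResult:
    design: str
    threshold: float
    detections: pd.DataFrame  # replicate, model, qtl marker, success, distance_cm
    false_positives: pd.DataFrame  # replicate, model, n_false
    n_null_markers: int
    n_replicates: int
    seed: int
    errors: pd.DataFrame  # replicate, model, message (empty when clean)


@dataclass
class PerformanceSummary:
    power: pd.DataFrame  # model x qtl
    resolution: pd.DataFrame  # mean distance among successful replicates
    resolution_all: pd.DataFrame  # mean distance over all replicates with a peak
    false_positive_total: pd.Series  # per model
    expected_false_positives: float


def expected_false_positives(n_null_markers: int, n_runs: int, threshold: float) -> float:
    """Expected super-threshold marker count on the QTL-free chromosome:
    m * R * 10^-T under per-marker uniform p-values."""
    return float(n_null_markers * n_runs * 10.0 ** (-threshold))


def false_positive_count(
    profiles: ScanProfile | list[ScanProfile], null_chrom: str, threshold: float
) -> list[int]:
    """Markers exceeding the threshold on the QTL-free chromosome, per profile."""
    if not isinstance(profiles, list):
        profiles = [profiles]
    counts = []
    for pr in profiles:
        sub = pr.table[(pr.table["chrom"] == str(null_chrom)) & pr.table["tested"]]
        counts.append(int((sub["minus_log10_p"] > threshold).sum()))
    return counts


def run_replication_study(
    design: str,
    models: list[str],
    n_replicates: int,
    threshold: float = 4.2,
    seed: int = 0,
    n_per_family: int | None = None,
    missing_rate: float = 0.05,
    error_rate: float = 0.005,
    step: int = 1,
    window_cm: float = 20.0,
    exclusion_cm: float = 20.0,
    n_calibration: int = 100,
) -> ReplicationResult:
    """Run the full pipeline over independent simulated replicates.

    Deterministic given ``seed``: replicate r uses the child stream
    (seed, r) of a NumPy seed sequence. Stage failures are recorded per
    replicate instead of aborting the study.
    """
    from .simulate import default_map, default_plan, simulate_study

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    gmap = default_map()
    plan = default_plan(design)
    rho = calibrate_junction_density(
        plan, gmap, n_calibration, np.random.default_rng([seed, 987654321])
    )
    det_rows, fp_rows, err_rows = [], [], []
    n_null = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        plan_r, founders, arch, mosaics, genotypes, trait = simulate_study(
            design, rng, n_per_family=n_per_family, missing_rate=missing_rate
        )
        tensor = ibd_posteriors(plan_r, founders, genotypes, rho, error_rate)
        kinships = loco_kinship(
            genotypes.dosages, gmap, individuals=genotypes.individuals
        )
        ctx = ScanContext(
            trait.y, plan_r, tensor, kinships=kinships, dosages=genotypes.dosages
        )
        truth = arch.majors
        null_chrom = arch.null_chrom
        n_null = int((gmap.table["chrom"] == null_chrom).sum())
        for model in models:
            try:
                profile, _ = mqm_iterate(
                    ctx,
                    model,
                    threshold,
                    step=step,
                    exclusion_cm=exclusion_cm,
                    ibs_fast=True,
                )
                outcome = call_qtls_and_success(profile, truth, threshold, window_cm)
                for _, row in outcome.iterrows():
                    det_rows.append(
                        {
                            "replicate": rep,
                            "model": model,
                            "qtl": row["marker"],
                            "success": bool(row["success"]),
                            "distance_cm": row["distance_cm"],
                            "peak_value": row["peak_value"],
                        }
                    )
                fp_rows.append(
                    {
                        "replicate": rep,
                        "model": model,
                        "n_false": false_positive_count(profile, null_chrom, threshold)[0],
                    }
                )
            except Exception as exc:  # noqa: BLE001 - per-replicate bookkeeping
                err_rows.append({"replicate": rep, "model": model, "message": str(exc)})
    return ReplicationResult(
        design=design,
        threshold=threshold,
        detections=pd.DataFrame(det_rows),
        false_positives=pd.DataFrame(fp_rows),
        n_null_markers=n_null,
        n_replicates=n_replicates,
        seed=seed,
        errors=pd.DataFrame(err_rows, columns=["replicate", "model", "message"]),
    )


def summarize_performance(result: ReplicationResult) -> PerformanceSummary:
    """Aggregate a replication study into power/resolution/false-positive tables.

    Resolution is reported twice: averaged over successful replicates (the
    headline convention) and over all replicates where the chromosome had a
    tested peak.
    """
    det = result.detections
    if det.empty:
        raise ValueError("empty replication result")
    power = det.pivot_table(index="model", columns="qtl", values="success", aggfunc="mean")
    ok = det[det["success"]]
    resolution = ok.pivot_table(
        index="model", columns="qtl", values="distance_cm", aggfunc="mean"
    )
    resolution_all = det.dropna(subset=["distance_cm"]).pivot_table(
        index="model", columns="qtl", values="distance_cm", aggfunc="mean"
    )
    fp_total = result.false_positives.groupby("model")["n_false"].sum()
    expected = expected_false_positives(
        result.n_null_markers, result.n_replicates, result.threshold
    )
    return PerformanceSummary(power, resolution, resolution_all, fp_total, expected)


def plot_performance(summary: PerformanceSummary, path=None):
    """Grouped bar charts: mapping power (top) and resolution (bottom),
    one group per major QTL, one bar per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for ax, frame, label in (
        (axes[0], summary.power, "mapping power"),
        (axes[1], summary.resolution, "resolution (cM)"),
    ):
        frame.T.plot.bar(ax=ax, rot=0, legend=ax is axes[0])
        ax.set_ylabel(label)
    axes[1].set_xlabel("simulated major QTL")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
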