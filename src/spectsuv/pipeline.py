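"""Stage chaining and the analysis report.

``run_quantify`` turns activity volumes plus patient records into a lesion
table (SUV conversion, then iterative global-maximum extraction, then
category/region labelling from a sidecar file).  ``run_analyze`` runs the
full statistical chain on a lesion table and assembles an
:class:`AnalysisReport`, the JSON-serialisable record of every cohort
result: per-category summaries, region distribution, normality, the
Mann-Whitney comparison, ROC/AUC with its confidence interval, the Youden
cut-off, bin breakdowns and the overlap interval.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort_stats import (BIN_EDGES, auc_ci, bin_breakdown, empirical_roc,
                           mann_whitney, overlap_range, region_distribution,
                           shapiro_wilk, summarize, youden_cutoff)
from .quantification import ActivityVolume, PatientRecord, suv_volume
from .segmentation import extract_lesions

logger = logging.getLogger("spectsuv")

__all__ = ["AnalysisReport", "run_quantify", "run_analyze",
            "report_to_markdown"]


class CategorySummary(BaseModel):
    n: int
    min: float
    max: float
    mean: float
    sd: float


class RegionRow(BaseModel):
    count: int
    percent: float


class RocSummary(BaseModel):
    auc: float
    ci_low: float
    ci_high: float


class CutoffSummary(BaseModel):
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


class BinSummary(BaseModel):
    edges: list[float]
    counts: list[int]
    percentages: list[float]


class OverlapSummary(BaseModel):
    low: float | None
    high: float | None
    count_inside: int
    fraction_inside: float


class Provenance(BaseModel):
    seed: int | None = None
    config: dict = Field(default_factory=dict)
    package: str = "spectsuv"
    version: str = ""


class AnalysisReport(BaseModel):
    """Full cohort analysis: summaries through overlap, plus provenance."""

    summaries: dict[str, CategorySummary]
    regions: dict[str, RegionRow]
    shapiro_p: dict[str, float]
    mann_whitney_u: float
    mann_whitney_p: float
    roc: RocSummary
    cutoff: CutoffSummary
    bins: dict[str, BinSummary]
    overlap: OverlapSummary
    n_unlabeled_excluded: int = 0
    provenance: Provenance

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = self.model_dump_json(indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        return cls.model_validate_json(Path(path).read_text())


def run_quantify(volumes: dict[str, ActivityVolume],
                 patients: list[PatientRecord],
                 labels: pd.DataFrame | None = None,
                 half_life_h: float = 6.0067,
                 frac: float = 0.40,
                 radius_mm: float = 15.0,
                 k_max: int = 5,
                 floor: float | None = None,
                 match_radius_mm: float = 20.0) -> pd.DataFrame:
    """Quantify volumes into a lesion table.

    ``volumes`` maps patient_id to an activity volume.  ``labels`` is the
    sidecar table (patient_id, seed_i/j/k, category, region); each
    extracted VOI is matched to the nearest labelled seed within
    ``match_radius_mm``, else emitted with category "unlabeled" and a
    warning.  Raises if a volume has no matching patient record.
    """
    by_id = {p.patient_id: p for p in patients}
    rows = []
    if not volumes:
        logger.warning("run_quantify: empty volume list")
    for patient_id, vol in volumes.items():
        if patient_id not in by_id:
            raise KeyError(f"no patient record for volume {patient_id!r}")
        patient = by_id[patient_id]
        suv = suv_volume(vol, patient, half_life_h)
        vois = extract_lesions(suv, k_max=k_max, frac=frac,
                               radius_mm=radius_mm, floor=floor)
        plabels = (labels[labels["patient_id"] == patient_id]
                   if labels is not None else None)
        for rank, voi in enumerate(vois, start=1):
            category, region = _match_label(
                voi, plabels, suv.voxel_spacing_mm, match_radius_mm)
            if category == "unlabeled":
                logger.warning("patient %s: VOI at %s has no label within "
                               "%.0f mm", patient_id, voi.seed_voxel,
                               match_radius_mm)
            rows.append({
                "patient_id": patient_id,
                "lesion_id": f"{patient_id}-V{rank}",
                "category": category,
                "region": region,
                "suv_max": voi.suv_max,
                "seed_i": voi.seed_voxel[0],
                "seed_j": voi.seed_voxel[1],
                "seed_k": voi.seed_voxel[2],
            })
        logger.info("patient %s: %d VOIs extracted", patient_id, len(vois))
    return pd.DataFrame(
        rows, columns=["patient_id", "lesion_id", "category", "region",
                       "suv_max", "seed_i", "seed_j", "seed_k"])


def _match_label(voi, plabels, spacing, match_radius_mm):
    if plabels is None or len(plabels) == 0:
        return "unlabeled", "O"
    seed_mm = np.array([i * s for i, s in zip(voi.seed_voxel, spacing)])
    label_mm = plabels[["seed_i", "seed_j", "seed_k"]].to_numpy(float) \
        * np.asarray(spacing)
    dist = np.linalg.norm(label_mm - seed_mm, axis=1)
    best = int(np.argmin(dist))
    if dist[best] > match_radius_mm:
        return "unlabeled", "O"
    row = plabels.iloc[best]
    return str(row["category"]), str(row.get("region", "O"))


def run_analyze(table: pd.DataFrame,
                seed: int | None = None,
                config: dict | None = None,
                bin_edges: tuple[float, float] = BIN_EDGES,
                ci_level: float = 0.95) -> AnalysisReport:
    """Run the full statistical chain on a lesion table.

    Rows labelled "unlabeled" are excluded (count logged and reported).
    Raises if the table does not contain both lesion categories.
    """
    n_unlabeled = int((table["category"] == "unlabeled").sum())
    if n_unlabeled:
        logger.info("excluding %d unlabeled lesions", n_unlabeled)
    work = table[table["category"] != "unlabeled"]
    met = work.loc[work["category"] == "metastatic", "suv_max"].to_numpy(float)
    deg = work.loc[work["category"] == "degenerative",
                   "suv_max"].to_numpy(float)
    if met.size == 0 or deg.size == 0:
        raise ValueError("analysis requires both metastatic and degenerative "
                         "lesions in the table")

    scores = np.concatenate([met, deg])
    labels = np.concatenate([np.ones(met.size, bool),
                             np.zeros(deg.size, bool)])
    u, p = mann_whitney(met, deg)
    roc = empirical_roc(scores, labels)
    lo, hi = auc_ci(scores, labels, level=ci_level)
    cut = youden_cutoff(roc)
    interval, count_inside, fraction = overlap_range(met, deg)

    region_df = region_distribution(work)
    summaries = {"metastatic": summarize(met), "degenerative": summarize(deg)}
    report = AnalysisReport(
        summaries={k: CategorySummary(**vars(s))
                   for k, s in summaries.items()},
        regions={r: RegionRow(count=int(region_df.loc[r, "count"]),
                              percent=float(region_df.loc[r, "percent"]))
                 for r in region_df.index},
        shapiro_p={"metastatic": shapiro_wilk(met)[1],
                   "degenerative": shapiro_wilk(deg)[1]},
        mann_whitney_u=u,
        mann_whitney_p=p,
        roc=RocSummary(auc=roc.auc, ci_low=lo, ci_high=hi),
        cutoff=CutoffSummary(threshold=cut.threshold,
                             sensitivity=cut.sensitivity,
                             specificity=cut.specificity,
                             youden_j=cut.youden_j),
        bins={"metastatic": _bin_summary(met, bin_edges),
              "degenerative": _bin_summary(deg, bin_edges)},
        overlap=OverlapSummary(
            low=None if interval is None else interval[0],
            high=None if interval is None else interval[1],
            count_inside=count_inside, fraction_inside=fraction),
        n_unlabeled_excluded=n_unlabeled,
        provenance=Provenance(seed=seed, config=config or {},
                              version=__version__),
    )
    logger.info("analyzed %d metastatic + %d degenerative lesions",
                met.size, deg.size)
    return report


def _bin_summary(values, edges) -> BinSummary:
    b = bin_breakdown(values, edges=tuple(edges))
    return BinSummary(edges=list(edges), counts=list(b.counts),
                      percentages=list(b.percentages))


def report_to_markdown(report: AnalysisReport) -> str:
    """Render an AnalysisReport as a short markdown document."""
    lines = ["# SUVmax cohort analysis", ""]
    lines.append("## Lesion summaries (SUVmax, g/mL)")
    lines.append("| category | n | min | max | mean | sd |")
    lines.append("|---|---|---|---|---|---|")
    for cat, s in report.summaries.items():
        lines.append(f"| {cat} | {s.n} | {s.min:.2f} | {s.max:.2f} "
                     f"| {s.mean:.2f} | {s.sd:.2f} |")
    lines.append("")
    lines.append("## Region distribution")
    lines.append("| region | count | percent |")
    lines.append("|---|---|---|")
    for r, row in report.regions.items():
        lines.append(f"| {r} | {row.count} | {row.percent:.2f}% |")
    lines += [
        "",
        "## Tests",
        f"- Shapiro-Wilk p: metastatic {report.shapiro_p['metastatic']:.2e},"
        f" degenerative {report.shapiro_p['degenerative']:.2e}",
        f"- Mann-Whitney U = {report.mann_whitney_u:.1f},"
        f" two-sided p = {report.mann_whitney_p:.2e}",
        f"- AUC = {report.roc.auc:.3f}"
        f" (95% CI {report.roc.ci_low:.3f}-{report.roc.ci_high:.3f})",
        f"- Youden cut-off: SUVmax > {report.cutoff.threshold:.2f} g/mL"
        f" (sensitivity {report.cutoff.sensitivity:.1%},"
        f" specificity {report.cutoff.specificity:.1%})",
        "",
        "## Overlap",
    ]
    if report.overlap.low is None:
        lines.append("- no overlap between categories")
    else:
        lines.append(
            f"- overlap interval [{report.overlap.low:.2f}, "
            f"{report.overlap.high:.2f}] g/mL contains "
            f"{report.overlap.count_inside} lesions "
            f"({report.overlap.fraction_inside:.1%} of all)")
    for cat, b in report.bins.items():
        lines.append(
            f"- {cat} bins <{b.edges[0]:.0f} / {b.edges[0]:.0f}-"
            f"{b.edges[1]:.0f} / >={b.edges[1]:.0f} g/mL: "
            + " / ".join(f"{c} ({pct}%)"
                         for c, pct in zip(b.counts, b.percentages)))
    lines.append("")
    return "\n".join(lines)
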