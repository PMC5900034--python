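"""Config-driven orchestration of the full study analysis.

Fixed stage order: load/simulate → (calibrate) → exclude → align
(global RSPA, then custom intervals) → PQN → log → PCA with
bi-cross-validated rank → MMC + leave-mouse-out CV per label scheme →
pairwise ANOVA/FDR biomarker tables → significance profiles. Every
artifact is regenerable from the config + seed alone; a provenance
record (ordered steps, parameters, package version, config hash)
accompanies the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import nmrage
from nmrage.containers import SpectraMatrix, read_spectra, write_spectra
from nmrage.synthetic import CohortDesign, simulate_cohort, design_from_yaml
from nmrage.preprocess import (
    CALIBRATION_PRESETS, calibrate_matrix, exclude_regions, pqn_normalize,
    log_transform,
)
from nmrage.align import AlignmentParams, rspa, align_interval
from nmrage.multivariate import (
    CVPipelineSpec, bcv_rank, pca, leave_mouse_out_cv,
)
from nmrage.univariate import (
    build_biomarker_table, load_annotation_windows, significance_profile,
)

#: citrate and taurine windows — the signals with the largest pH-driven
#: shift variation in urine
DEFAULT_CUSTOM_INTERVALS = [(2.50, 2.75), (3.20, 3.50)]


@dataclass
class StudyConfig:
    """Everything needed to (re)run a study analysis."""

    design: CohortDesign | None = None  # simulate ...
    matrix_path: str | None = None  # ... or load
    metadata_path: str | None = None
    fluid: str = "urine"
    calibrate: bool = False
    align: bool = True
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    custom_intervals: list = field(default_factory=lambda: list(DEFAULT_CUSTOM_INTERVALS))
    pqn_reference: str = "median"
    log_offset: float | str = "auto"
    multivariate: bool = True
    max_rank: int = 10
    bcv_folds: int = 2
    shrinkage: float = 0.1
    cv_select_features: bool = True
    label_schemes: list = field(default_factory=lambda: ["genotype"])
    group_key: str = "mouse_id"
    fdr_adjacent: float = 0.1
    fdr_first_last: float = 0.05
    comparisons: list = field(default_factory=list)  # (sel_a, sel_b, fdr, label)
    annotation_path: str | None = None
    use_default_annotations: bool = True
    out_dir: str | None = None
    seed: int = 0

    def source(self) -> str:
        if self.design is not None:
            return "simulate"
        if self.matrix_path and self.metadata_path:
            return "load"
        raise ValueError("config needs either a design or matrix+metadata paths")


@dataclass
class StudyReport:
    matrices: dict  # stage name -> SpectraMatrix
    dilution_factors: pd.Series
    alignment_records: pd.DataFrame
    pca_model: object | None
    pca_rank: int
    trajectory: pd.DataFrame | None
    cv_reports: dict
    biomarker_tables: list
    profiles: dict
    provenance: dict


def _config_hash(config: StudyConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    doc = asdict(config)
    doc.pop("out_dir", None)  # where results land is not part of the analysis
    blob = json.dumps(doc, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _scheme_labels(meta: pd.DataFrame, scheme: str) -> np.ndarray:
    if scheme == "genotype":
        return meta["genotype"].to_numpy()
    if scheme == "week":
        return meta["week"].astype(str).to_numpy()
    if scheme in ("genotype:week", "genotype_week"):
        return (meta["genotype"] + ":" + meta["week"].astype(str)).to_numpy()
    raise ValueError(f"unknown label scheme {scheme!r}")


def _default_comparisons(meta: pd.DataFrame, fdr_adjacent: float,
                         fdr_first_last: float) -> list:
    weeks = sorted(meta["week"].astype(str).unique(), key=lambda w: float(w))
    comps = []
    for geno in sorted(meta["genotype"].unique()):
        for w0, w1 in zip(weeks, weeks[1:]):
            comps.append((
                {"genotype": geno, "week": w1}, {"genotype": geno, "week": w0},
                fdr_adjacent, f"{geno} {w1} vs. {w0}",
            ))
        if len(weeks) > 2:
            comps.append((
                {"genotype": geno, "week": weeks[-1]},
                {"genotype": geno, "week": weeks[0]},
                fdr_first_last, f"{geno} {weeks[-1]} vs. {weeks[0]}",
            ))
    return comps


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study analysis; see the module docstring."""
    stages: dict[str, SpectraMatrix] = {}
    provenance = {
        "version": nmrage.__version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
    }

    def record(stage, **params):
        provenance["stages"].append({"stage": stage, **params})

    if config.source() == "simulate":
        matrix, truth = simulate_cohort(config.design)
        record("simulate", seed=config.design.seed)
    else:
        matrix = read_spectra(config.matrix_path, config.metadata_path)
        truth = None
        record("load", matrix=config.matrix_path)
    matrix = matrix.sort_samples()
    stages["raw"] = matrix

    if config.calibrate:
        window, target = CALIBRATION_PRESETS[config.fluid]
        matrix = calibrate_matrix(matrix, window, target)
        record("calibrate", target=target)

    matrix = exclude_regions(matrix, config.fluid)
    record("exclude", preset=config.fluid)
    stages["excluded"] = matrix

    alignment_records = pd.DataFrame()
    if config.align:
        res = rspa(matrix, config.alignment)
        record("rspa", reference=res.reference_id)
        frames = [res.records]
        if config.custom_intervals:
            res = align_interval(
                res.matrix, config.custom_intervals, config.alignment,
                reference_id=res.reference_id,
            )
            record("align_interval", intervals=config.custom_intervals)
            frames.append(res.records)
        matrix = res.matrix
        alignment_records = pd.concat(frames, ignore_index=True)
    stages["aligned"] = matrix

    norm = pqn_normalize(matrix, config.pqn_reference)
    record("pqn", reference=norm.reference)
    matrix = log_transform(norm.matrix, config.log_offset)
    record("log", offset=matrix.log[-1]["offset"])
    stages["processed"] = matrix

    pca_model = None
    rank = 0
    trajectory = None
    cv_reports: dict = {}
    if config.multivariate:
        X = matrix.intensities
        cap = min(config.max_rank, matrix.n_samples - 2)
        rank = bcv_rank(X, config.bcv_folds, config.bcv_folds, cap, seed=config.seed)
        record("bcv_rank", selected=rank)
        pca_model = pca(X, max(rank, 2))  # >=2 axes for trajectory plots
        record("pca", rank=pca_model.rank)
        trajectory = _trajectory_frame(matrix.meta, pca_model)
        spec = CVPipelineSpec(
            select_features=config.cv_select_features,
            max_rank=max(rank, 2),
            shrinkage=config.shrinkage,
        )
        for scheme in config.label_schemes:
            y = _scheme_labels(matrix.meta, scheme)
            groups = matrix.meta[config.group_key].to_numpy()
            cv_reports[scheme] = leave_mouse_out_cv(X, y, groups, spec)
            record("leave_mouse_out_cv", scheme=scheme,
                   accuracy=cv_reports[scheme].accuracy)

    annotations = None
    if config.annotation_path:
        annotations = load_annotation_windows(config.annotation_path)
    elif config.use_default_annotations and config.fluid == "urine":
        annotations = load_annotation_windows()
    comparisons = config.comparisons or _default_comparisons(
        matrix.meta, config.fdr_adjacent, config.fdr_first_last
    )
    tables = []
    profiles = {}
    for sel_a, sel_b, fdr, label in comparisons:
        table = build_biomarker_table(
            matrix, (sel_a, sel_b), fdr=fdr,
            annotation_windows=annotations, label=label,
        )
        tables.append(table)
        profiles[label] = pd.DataFrame({
            "ppm": table.per_variable["ppm"],
            "difference": table.per_variable["mean_log_difference"],
            "p": table.per_variable["p"],
        })
        record("biomarker_table", label=label, fdr=fdr,
               threshold=table.bh_threshold)

    report = StudyReport(
        matrices=stages,
        dilution_factors=norm.dilution_factors,
        alignment_records=alignment_records,
        pca_model=pca_model,
        pca_rank=rank,
        trajectory=trajectory,
        cv_reports=cv_reports,
        biomarker_tables=tables,
        profiles=profiles,
        provenance=provenance,
    )
    if config.out_dir:
        _write_report(report, matrix, Path(config.out_dir))
    return report


def _trajectory_frame(meta: pd.DataFrame, pca_model) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": meta["sample_id"],
        "genotype": meta["genotype"],
        "week": meta["week"].astype(str),
        "PC1": pca_model.scores[:, 0],
        "PC2": pca_model.scores[:, 1],
    })


def trajectory_scores(report: StudyReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample PC1/PC2 scores plus per-(genotype, week) centroids and
    dispersion (mean pairwise within-group score distance), for the ageing
    trajectory plot."""
    if report.trajectory is None:
        raise ValueError("PCA stage was not run; no trajectory available")
    scores = report.trajectory
    rows = []
    for (geno, week), grp in scores.groupby(["genotype", "week"], sort=True):
        pts = grp[["PC1", "PC2"]].to_numpy()
        if pts.shape[0] > 1:
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            disp = float(d[np.triu_indices(pts.shape[0], 1)].mean())
        else:
            disp = 0.0
        rows.append({
            "genotype": geno, "week": week,
            "PC1": float(pts[:, 0].mean()), "PC2": float(pts[:, 1].mean()),
            "dispersion": disp, "n": pts.shape[0],
        })
    return scores, pd.DataFrame(rows)


def _write_report(report: StudyReport, matrix: SpectraMatrix, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_spectra(matrix, out / "processed_matrix.csv", out / "metadata.tsv")
    report.dilution_factors.rename_axis("sample_id").to_csv(
        out / "dilution_factors.tsv", sep="\t", float_format="%.12g"
    )
    if len(report.alignment_records):
        report.alignment_records.to_csv(
            out / "alignment_shifts.tsv", sep="\t", index=False, float_format="%.12g"
        )
    if report.trajectory is not None:
        scores, centroids = trajectory_scores(report)
        scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False, float_format="%.12g")
        centroids.to_csv(out / "pca_centroids.tsv", sep="\t", index=False, float_format="%.12g")
    for scheme, cv in report.cv_reports.items():
        payload = {
            "scheme": scheme,
            "accuracy": cv.accuracy,
            "predicted_variance": cv.predicted_variance,
            "confusion": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in cv.confusion.to_dict(orient="index").items()
            },
            "warnings": cv.warnings,
        }
        (out / f"cv_{scheme.replace(':', '_')}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
    for table in report.biomarker_tables:
        slug = table.comparison.replace(" ", "_").replace(".", "").replace("/", "-")
        table.per_variable.to_csv(
            out / f"variables_{slug}.tsv", sep="\t", index=False, float_format="%.12g"
        )
        if len(table.per_metabolite):
            table.per_metabolite.to_csv(
                out / f"metabolites_{slug}.tsv", sep="\t", index=False,
                float_format="%.12g",
            )
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True, default=str)
    )


# -- YAML config -------------------------------------------------------

def config_from_yaml(path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file. The ``design`` key
    may point at a cohort-design YAML (see the synthetic module)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    design = None
    if "design" in doc:
        design = design_from_yaml(doc.pop("design"))
    align_doc = doc.pop("alignment", None)
    config = StudyConfig(design=design, **doc)
    if align_doc:
        config.alignment = AlignmentParams(**align_doc)
    if config.custom_intervals:
        config.custom_intervals = [tuple(iv) for iv in config.custom_intervals]
    return config
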