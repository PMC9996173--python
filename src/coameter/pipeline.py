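"""End-to-end orchestration: measure -> diagnose -> evaluate."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .config import PipelineConfig
from .diagnosis import diagnose
from .errors import CoameterError, SchemaError
from .evaluation import confusion, interpret_kappa, metrics, wilcoxon_signed_rank
from .morphometry import DiameterSearchParams, ScaleCalibration, measure
from .phantoms import SITES

log = logging.getLogger("coameter")


@dataclass
class RunReport:
    """Everything a pipeline run produced, JSON-serialisable via to_dict()."""

    config: dict
    measurements: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)
    evaluation: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "measurements": self.measurements,
            "failures": self.failures,
            "evaluation": self.evaluation,
        }


def measure_images(paths: list[str | Path], config: PipelineConfig) -> tuple[list[dict], list[dict]]:
    """Measure each image, collecting per-image failures without aborting."""
    cal = ScaleCalibration(config.mm_per_px)
    params = DiameterSearchParams(slope_abs_tol=config.slope_abs_tol)
    rows: list[dict] = []
    failures: list[dict] = []
    for p in paths:
        try:
            img = io.read_image(p)
            m = measure(img, cal, params, config.ranges())
            rows.append(
                {
                    "image": str(p),
                    "diameter_px": m.diameter_px,
                    "diameter_mm": m.diameter_mm,
                    "centroid_x": m.centroid.x,
                    "centroid_y": m.centroid.y,
                    "n_candidates": m.n_candidates,
                    "warnings": m.warnings,
                }
            )
            log.info("measured %s: %.2f px / %.3f mm", p, m.diameter_px, m.diameter_mm)
        except (OSError, ValueError, CoameterError) as exc:
            failures.append({"image": str(p), "error": f"{type(exc).__name__}: {exc}"})
            log.error("failed on %s: %s", p, exc)
    return rows, failures


def diagnose_cohort(cohort: pd.DataFrame, criteria: list[str]) -> pd.DataFrame:
    """Predictions table for every subject x method x requested criterion."""
    if "karl" in criteria and "weight_kg" not in cohort.columns:
        raise SchemaError("Karl's criterion requires column 'weight_kg'")
    rows = []
    for method in sorted(cohort["method"].unique()):
        for sid, m in io.subject_measurements(cohort, method, require_weight="karl" in criteria):
            for crit in criteria:
                r = diagnose(m, crit)
                rows.append(
                    {
                        "subject_id": sid,
                        "method": method,
                        "criterion": crit,
                        "predicted_label": r.label,
                        "triggered_conditions": ";".join(r.triggered),
                    }
                )
    return pd.DataFrame(rows, columns=io.PREDICTION_COLUMNS)


def evaluate_predictions(predictions: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """Per method x criterion confusion matrix, metrics and kappa grade."""
    truth = cohort.drop_duplicates("subject_id").set_index("subject_id")["group"]
    out: dict = {}
    for (method, crit), grp in predictions.groupby(["method", "criterion"], sort=True):
        g = grp.set_index("subject_id")
        cm = confusion(g["predicted_label"], truth.loc[g.index])
        em = metrics(cm).rounded()
        out.setdefault(method, {})[crit] = {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "accuracy": em.accuracy,
            "sensitivity": em.sensitivity,
            "specificity": em.specificity,
            "auc": em.auc,
            "kappa": em.kappa,
            "agreement": interpret_kappa(em.kappa),
        }
    return out


def compare_methods(cohort: pd.DataFrame) -> dict:
    """Wilcoxon signed-rank p-values between methods, per group and site."""
    out: dict = {}
    wide = cohort.pivot_table(
        index=["group", "subject_id", "site"], columns="method", values="diameter_mm"
    ).reset_index()
    if not {"manual", "intelligent"} <= set(wide.columns):
        return out
    for (group, site), grp in wide.groupby(["group", "site"], sort=True):
        try:
            res = wilcoxon_signed_rank(grp["manual"].to_numpy(), grp["intelligent"].to_numpy())
            out.setdefault(group, {})[site] = {
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": res.n_used,
                "method": res.method,
            }
        except ValueError as exc:
            out.setdefault(group, {})[site] = {"error": str(exc)}
    return out


def run_pipeline(
    config: PipelineConfig,
    image_paths: list[str | Path] | None = None,
    cohort: pd.DataFrame | None = None,
) -> RunReport:
    """Run measure -> diagnose -> evaluate on whatever inputs are given.

    Per-image failures are recorded and the run continues; ``report.ok``
    is False if anything failed.
    """
    report = RunReport(config=asdict(config))
    if image_paths:
        report.measurements, report.failures = measure_images(list(image_paths), config)
    if cohort is not None and len(cohort):
        predictions = diagnose_cohort(cohort, list(config.criteria))
        report.evaluation = {
            "diagnostics": evaluate_predictions(predictions, cohort),
            "method_comparison": compare_methods(cohort),
            "n_subjects": int(cohort["subject_id"].nunique()),
            "sites": list(SITES),
        }
    return report
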