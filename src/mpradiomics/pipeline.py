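"""End-to-end orchestration: simulate -> extract -> screen -> classify -> report.

A single JSON-serializable :class:`PipelineConfig` drives every stage; all
randomness flows from its master seed, so rerunning the same config
reproduces every tabular output byte for byte.  Each stage reads only the
config and the previous stage's files, and the run directory carries a
MANIFEST.json with the config hash for audit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    RFConfig,
    TASK_LABELS,
    crossval_rf,
    holdout_rf,
    run_modality_comparison,
)
from .extraction import FEATURE_MODES, extract_cohort_tables
from .features import CohortFeatureTable
from .imaging import read_volume
from .screening import screen_features
from .synthetic import CohortSpec, SyntheticPatient, generate_cohort, read_lesion_table, write_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    out_dir: str = "run"
    seed: int = 0
    input_dir: str | None = None          # None -> synthetic cohort
    n_per_group: int = 30
    volume_shape: tuple[int, int, int] = (64, 64, 19)
    blob_scale_per_group: tuple[float, float, float] = (9.0, 5.0, 2.0)
    noise_sd: float = 0.05
    grouping: str = "three"
    modes: tuple[str, ...] = ("mean", "T2", "ADC")
    alpha: float = 0.05
    scale: bool = True
    ng: int = 32
    normalization: str = "minmax"
    rf: RFConfig = field(default_factory=RFConfig)
    holdout_train: int = 40
    holdout_test: int = 20

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one feature mode is required")
        bad = [m for m in self.modes if m not in FEATURE_MODES]
        if bad:
            raise ValueError(f"unknown feature modes: {bad}")
        if isinstance(self.rf, dict):
            self.rf = RFConfig(**self.rf)
        self.modes = tuple(self.modes)
        self.volume_shape = tuple(self.volume_shape)
        self.blob_scale_per_group = tuple(self.blob_scale_per_group)
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        rf_seed_offset = 0  # cohort and model seeds share the master seed
        return CohortSpec(
            n_per_group=self.n_per_group,
            volume_shape=self.volume_shape,
            blob_scale_per_group=self.blob_scale_per_group,
            noise_sd=self.noise_sd,
            seed=self.seed + rf_seed_offset,
        )

    def rf_config(self) -> RFConfig:
        return dataclasses.replace(self.rf, seed=self.seed)


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{produced_by}' stage first"
        )
    return path


def stage_simulate(cfg: PipelineConfig) -> Path:
    """Write a synthetic cohort under <out_dir>/cohort."""
    cohort_dir = _out(cfg) / "cohort"
    patients = generate_cohort(cfg.cohort_spec())
    manifest = write_cohort(patients, cohort_dir, overwrite=True)
    logger.info("simulated %d patients into %s", len(patients), cohort_dir)
    return manifest


def _load_patients(cohort_dir: Path) -> list[SyntheticPatient]:
    manifest_path = _require(cohort_dir / "manifest.json", "simulate")
    manifest = json.loads(manifest_path.read_text())
    lesions = {
        r.patient_id: r
        for r in read_lesion_table(cohort_dir / manifest["lesion_table"])
    }
    patients = []
    for pid, paths in manifest["volumes"].items():
        lesion = lesions[pid]
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                t2_volume=read_volume(cohort_dir / paths["T2"], "T2"),
                adc_volume=read_volume(cohort_dir / paths["ADC"], "ADC"),
                lesion=lesion,
                true_group=lesion.group,
            )
        )
    patients.sort(key=lambda p: p.patient_id)
    return patients


def stage_extract(cfg: PipelineConfig) -> dict[str, Path]:
    """Read the cohort and write one feature CSV per feature mode."""
    out = _out(cfg)
    cohort_dir = Path(cfg.input_dir) if cfg.input_dir else out / "cohort"
    if not (cohort_dir / "manifest.json").exists():
        raise FileNotFoundError(
            f"no cohort manifest in {cohort_dir}; run 'simulate' first "
            "or point input_dir at a cohort directory"
        )
    patients = _load_patients(cohort_dir)
    tables = extract_cohort_tables(
        patients, modes=cfg.modes, ng=cfg.ng, scale=cfg.scale,
        grouping=cfg.grouping, normalization=cfg.normalization,
    )
    paths = {}
    for mode, table in tables.items():
        path = out / f"features_{mode}.csv"
        table.to_frame().to_csv(
            path, index_label="patient_id", float_format=_FLOAT_FMT
        )
        paths[mode] = path
    return paths


def _load_table(cfg: PipelineConfig, mode: str) -> CohortFeatureTable:
    path = _require(_out(cfg) / f"features_{mode}.csv", "extract")
    frame = pd.read_csv(path, index_col="patient_id")
    return CohortFeatureTable.from_frame(frame, scaled=cfg.scale)


def stage_screen(cfg: PipelineConfig) -> dict[str, Path]:
    """Univariate screening of the primary (first-listed) feature mode."""
    out = _out(cfg)
    table = _load_table(cfg, cfg.modes[0])
    results, summary = screen_features(table, alpha=cfg.alpha)
    paths = {
        "univariate": out / "univariate.csv",
        "group_summary": out / "group_summary.csv",
        "heatmap": out / "screen_heatmap.csv",
    }
    results.to_csv(paths["univariate"], float_format=_FLOAT_FMT)
    summary.to_frame().to_csv(paths["group_summary"], float_format=_FLOAT_FMT)
    results[["neglog10_p_kw", "rho"]].to_csv(
        paths["heatmap"], float_format=_FLOAT_FMT
    )
    return paths


def stage_classify(cfg: PipelineConfig) -> dict[str, Path]:
    """One-vs-rest CV + hold-out + importance for every feature mode."""
    out = _out(cfg)
    rf_cfg = cfg.rf_config()
    tables = {m: _load_table(cfg, m) for m in cfg.modes}
    primary = cfg.modes[0]
    metrics: dict[str, dict] = {}
    importance_cols = {}
    roc_rows = []
    for target in sorted(set(tables[primary].groups)):
        if (tables[primary].groups == target).sum() < rf_cfg.n_folds:
            logger.warning("skipping CV for group %s: too few members", target)
            continue
        res = crossval_rf(tables[primary], int(target), rf_cfg)
        task = res.task
        metrics[task] = {
            "per_fold": res.fold_metrics[
                ["auc", "accuracy", "npv", "ppv"]
            ].round(10).to_dict(orient="list"),
            "mean": res.mean_metrics.round(10).to_dict(),
            "confusion": res.confusion,
        }
        importance_cols[task] = res.importance
        y = (tables[primary].groups == target).astype(int)
        order = np.argsort(-res.oof_scores.to_numpy(), kind="stable")
        scores_sorted = res.oof_scores.to_numpy()[order]
        labels_sorted = y.to_numpy()[order]
        tps = np.cumsum(labels_sorted)
        fps = np.cumsum(1 - labels_sorted)
        roc = pd.DataFrame(
            {
                "task": task,
                "threshold": scores_sorted,
                "tpr": tps / max(int(y.sum()), 1),
                "fpr": fps / max(int((1 - y).sum()), 1),
            }
        )
        roc_rows.append(roc)
    paths = {
        "cv_metrics": out / "cv_metrics.json",
        "importance": out / "importance.csv",
        "roc_points": out / "roc_points.csv",
        "holdout": out / "holdout_metrics.json",
        "modality_comparison": out / "modality_comparison.csv",
    }
    paths["cv_metrics"].write_text(json.dumps(metrics, indent=2, sort_keys=True))
    pd.DataFrame(importance_cols).to_csv(
        paths["importance"], float_format=_FLOAT_FMT
    )
    pd.concat(roc_rows, ignore_index=True).to_csv(
        paths["roc_points"], index=False, float_format=_FLOAT_FMT
    )
    # balanced hold-out validation, when the cohort is large enough
    holdout: dict[str, dict] = {}
    need = cfg.holdout_train // 2 + cfg.holdout_test // 2
    for target in sorted(set(tables[primary].groups)):
        target = int(target)
        label = TASK_LABELS.get(target, f"G{target}-vs-rest")
        y = (tables[primary].groups == target).astype(int)
        if y.sum() < need or (1 - y).sum() < need:
            holdout[label] = {
                "skipped": f"needs {need} patients per class"
            }
            continue
        holdout[label] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in holdout_rf(
                tables[primary], target, n_train=cfg.holdout_train,
                n_test=cfg.holdout_test, cfg=rf_cfg,
            ).items()
        }
    paths["holdout"].write_text(json.dumps(holdout, indent=2, sort_keys=True))
    if len(cfg.modes) > 1:
        try:
            comparison = run_modality_comparison(
                tables, cfg=rf_cfg, n_train=cfg.holdout_train,
                n_test=cfg.holdout_test,
            )
            comparison.to_csv(
                paths["modality_comparison"], index=False,
                float_format=_FLOAT_FMT,
            )
        except ValueError as exc:
            logger.warning("modality comparison skipped: %s", exc)
            paths.pop("modality_comparison")
    else:
        paths.pop("modality_comparison")
    return paths


def stage_report(cfg: PipelineConfig) -> Path:
    """Human-readable summary plus the MANIFEST.json audit record."""
    out = _out(cfg)
    uni_path = _require(out / "univariate.csv", "screen")
    cv_path = _require(out / "cv_metrics.json", "classify")
    uni = pd.read_csv(uni_path, index_col=0)
    cv = json.loads(cv_path.read_text())
    lines = [
        f"run directory : {out}",
        f"config hash   : {cfg.config_hash()}",
        f"master seed   : {cfg.seed}",
        f"grouping      : {cfg.grouping}",
        "",
        "Holm-significant features (Kruskal-Wallis):",
    ]
    sig = uni[uni["kw_significant"]]
    if len(sig) == 0:
        lines.append("  none")
    for name, row in sig.iterrows():
        lines.append(
            f"  {name}: H={row['H']:.2f} p_adj={row['p_kw_adj']:.2e} "
            f"rho={row['rho']:+.2f}"
        )
    lines.append("")
    lines.append("Cross-validated one-vs-rest performance (mean over folds):")
    for task in sorted(cv):
        m = cv[task]["mean"]
        lines.append(
            f"  {task}: AUC={m['auc']:.3f} acc={m['accuracy']:.3f} "
            f"NPV={m['npv']:.3f} PPV={m['ppv']:.3f}"
        )
    report_path = out / "summary.txt"
    report_path.write_text("\n".join(lines) + "\n")
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "outputs": sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "MANIFEST.json"
        ),
    }
    (out / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return report_path


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Run every stage in order and return the output paths."""
    paths: dict[str, object] = {}
    if cfg.input_dir is None:
        paths["cohort_manifest"] = stage_simulate(cfg)
    paths["features"] = stage_extract(cfg)
    paths["screen"] = stage_screen(cfg)
    paths["classify"] = stage_classify(cfg)
    paths["report"] = stage_report(cfg)
    return paths
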