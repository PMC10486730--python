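"""End-to-end orchestration: cohort I/O, configuration and the full run.

A run takes a directory of axial slices plus a cohort CSV (id, group,
age, sex, bmi, and the four DXA references), extracts one trabecular ROI
and 45-feature vector per subject, fits the linear (and optionally the
neural) model per group × target on the whole group, and writes feature
tables, model files, fit summaries, coefficient reports and the
between-group comparison — all a pure function of (inputs, config,
seed).  Timestamps appear only in the log so repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .core import (
    FEATURE_ORDER_VERSION,
    BonetexError,
    CohortSchemaError,
    CTSlice,
    InvalidParameterError,
    load_slice,
)
from .features import FEATURE_NAMES, extract_features, features_to_frame
from .models import ANNSpec, fit_ann, fit_lr, normalize
from .roi import ThresholdConfig, extract_roi
from .stats import (
    coefficient_pvalues,
    compare_groups,
    correlation_report,
)
from .synthetic import COHORT_COLUMNS, TARGETS

__all__ = [
    "PipelineConfig",
    "read_cohort_table",
    "run_pipeline",
    "analyze_cohort",
    "run_study",
]

REQUIRED_COLUMNS = list(COHORT_COLUMNS)
GROUPS = ("t2d", "normal")
MAX_SCAN_INTERVAL_DAYS = 31  # CT and DXA acquired less than a month apart
EXCLUSION_FLAGS = ("fracture", "metal_artifact", "osteolysis")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    slices_dir: str = "slices"
    cohort_csv: str = "cohort.csv"
    out_dir: str = "run"
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    glcm_offset_distance: int = 1
    glcm_symmetric: bool = True
    quantization: str = "minmax"
    model: str = "lr"  # "lr" | "ann" | "both"
    alpha: float = 0.05
    adjust_pvalues: bool = False
    univariate_pvalues: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidParameterError("alpha must be in (0, 1]")
        if self.model not in ("lr", "ann", "both"):
            raise InvalidParameterError("model must be lr, ann or both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("threshold", None)
        cfg = cls(**raw)
        if thr:
            cfg.threshold = ThresholdConfig(**thr)
        return cfg

    def config_hash(self) -> str:
        # hash the analysis parameters only, so runs of the same study to
        # different directories stamp (and reproduce) the same hash
        payload = dataclasses.asdict(self)
        for path_field in ("slices_dir", "cohort_csv", "out_dir"):
            payload.pop(path_field, None)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Enforces the documented schema, group labels in {t2d, normal} and
    strictly positive DXA references; rows whose optional
    ``scan_interval_days`` exceeds 31 days, or with a truthy exclusion
    flag (fracture, metal_artifact, osteolysis), are dropped and logged.
    """
    log = logging.getLogger("bonetex")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing columns: {missing}")

    bad_group = df.loc[~df["group"].isin(GROUPS), "id"].tolist()
    if bad_group:
        raise CohortSchemaError(f"unknown group label for ids: {bad_group}")
    nonpos = df.loc[(df[list(TARGETS)] <= 0).any(axis=1), "id"].tolist()
    if nonpos:
        raise CohortSchemaError(
            f"non-positive DXA reference for ids: {nonpos}"
        )

    if "scan_interval_days" in df.columns:
        drop = df["scan_interval_days"] > MAX_SCAN_INTERVAL_DAYS
        if drop.any():
            log.info(
                "excluding %d subjects with CT-DXA interval > %d days: %s",
                int(drop.sum()), MAX_SCAN_INTERVAL_DAYS,
                df.loc[drop, "id"].tolist(),
            )
            df = df.loc[~drop]
    for flag in EXCLUSION_FLAGS:
        if flag in df.columns:
            drop = df[flag].fillna(False).astype(bool)
            if drop.any():
                log.info(
                    "excluding %d subjects flagged %s: %s",
                    int(drop.sum()), flag, df.loc[drop, "id"].tolist(),
                )
                df = df.loc[~drop]
    return df.reset_index(drop=True)


def _extract_cohort_features(
    slices: list[CTSlice],
    table: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    log = logging.getLogger("bonetex")
    vectors = []
    for ct, sid in zip(slices, table["id"]):
        try:
            roi = extract_roi(ct, config.threshold)
            fv = extract_features(
                roi,
                offset_distance=config.glcm_offset_distance,
                symmetric=config.glcm_symmetric,
                quantization=config.quantization,
            )
        except BonetexError as exc:
            raise BonetexError(
                f"feature extraction failed for subject {sid}: {exc}"
            ) from exc
        vectors.append(fv)
    log.info("extracted %d feature vectors (%s quantization)",
             len(vectors), config.quantization)
    feats = features_to_frame(table["id"], vectors)
    feats.attrs["quantization"] = config.quantization
    return feats


def analyze_cohort(
    features: pd.DataFrame,
    table: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Fit per group × target and assemble every report, in memory.

    Returns a dict with keys ``fits`` ((target, group) → FitResult for
    the configured primary model), ``ann_fits`` (when requested),
    ``models``, ``reports`` (coefficient reports), ``comparison``
    (GroupComparison) and ``correlations`` (summary DataFrame).
    """
    log = logging.getLogger("bonetex")
    merged = features.merge(table, on="id", validate="one_to_one")
    F_cols = list(FEATURE_NAMES)

    fits: dict = {}
    ann_fits: dict = {}
    models: dict = {}
    reports: dict = {}
    for group in GROUPS:
        sub = merged[merged["group"] == group]
        if sub.empty:
            continue
        F = sub[F_cols].to_numpy()
        for target in TARGETS:
            y = sub[target].to_numpy()
            try:
                design = normalize(F, y)
            except BonetexError as exc:
                raise BonetexError(
                    f"stage fit ({group}/{target}): {exc}"
                ) from exc
            if config.model in ("lr", "both"):
                model, fit = fit_lr(design, target_name=target)
                models[(target, group)] = model
                fits[(target, group)] = fit
                reports[(target, group)] = coefficient_pvalues(
                    model,
                    design,
                    alpha=config.alpha,
                    adjust=config.adjust_pvalues,
                    group=group,
                    univariate=config.univariate_pvalues,
                )
            if config.model in ("ann", "both"):
                _, afit = fit_ann(
                    design, ANNSpec(seed=config.seed), target_name=target
                )
                ann_fits[(target, group)] = afit
            log.info("fitted %s/%s (n=%d)", group, target, len(sub))

    out = {
        "fits": fits if fits else ann_fits,
        "ann_fits": ann_fits,
        "models": models,
        "reports": reports,
        "correlations": correlation_report(fits if fits else ann_fits),
    }
    if reports:
        out["comparison"] = compare_groups(
            reports, alpha=config.alpha, use_adjusted=config.adjust_pvalues
        )
    return out


def _setup_log(out_dir: Path) -> logging.Logger:
    log = logging.getLogger("bonetex")
    log.setLevel(logging.INFO)
    for h in list(log.handlers):
        log.removeHandler(h)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    return log


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full file-based pipeline; returns the run directory.

    Artifacts: ``features.csv``, ``model_<target>_<group>.json``,
    ``coefficients_<target>_<group>.csv``, ``group_comparison.csv``,
    ``correlations.csv``, ``summary.txt``, ``manifest.json`` (config
    hash + feature-order version + per-stage counts) and ``run.log``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _setup_log(out_dir)
    log.info("run started (config hash %s)", config.config_hash())

    table = read_cohort_table(config.cohort_csv)
    n_read = len(table)
    slices_dir = Path(config.slices_dir)
    slices = []
    for sid in table["id"]:
        stem = slices_dir / str(sid)
        if not stem.with_suffix(".json").exists():
            raise BonetexError(f"stage load-slices: no slice for subject {sid}")
        slices.append(load_slice(stem))
    log.info("loaded %d slices from %s", len(slices), slices_dir)

    feats = _extract_cohort_features(slices, table, config)
    feats.to_csv(out_dir / "features.csv", index=False)

    results = analyze_cohort(feats, table, config)

    for (target, group), model in results["models"].items():
        model.to_json(out_dir / f"model_{target}_{group}.json")
    for (target, group), rep in results["reports"].items():
        rep.table.to_csv(
            out_dir / f"coefficients_{target}_{group}.csv", index=False
        )
    if "comparison" in results:
        results["comparison"].table.to_csv(
            out_dir / "group_comparison.csv", index=False
        )
    results["correlations"].to_csv(out_dir / "correlations.csv", index=False)

    lines = [
        f"bonetex run {config.config_hash()}",
        f"feature order: {FEATURE_ORDER_VERSION}",
        f"quantization: {config.quantization}",
        f"p-value mode: {'univariate' if config.univariate_pvalues else 'full multivariate fit'}"
        + (", Benjamini-Hochberg adjusted" if config.adjust_pvalues else ", raw"),
        "",
        results["correlations"].to_string(index=False),
    ]
    if "comparison" in results:
        lines.append("")
        for target, names in results["comparison"].discordant.items():
            lines.append(
                f"discordant (significant in exactly one group) for {target}: "
                + (", ".join(names) if names else "none")
            )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")

    manifest = {
        "config_hash": config.config_hash(),
        "feature_order_version": FEATURE_ORDER_VERSION,
        "seed": config.seed,
        "stage_counts": {
            "rows_read": n_read,
            "rows_analyzed": len(table),
            "slices_loaded": len(slices),
            "features_extracted": len(feats),
        },
        "generated": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run finished")
    return out_dir


def run_study(
    cohort_cfg: synthetic.CohortConfig | None = None,
    phantom_cfg: synthetic.PhantomConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Simulate a phantom cohort and analyze it entirely in memory.

    Convenience wrapper used by the acceptance script and tests; returns
    the :func:`analyze_cohort` result dict plus the cohort ``table``,
    ``features`` and ``truths``.
    """
    cohort_cfg = cohort_cfg if cohort_cfg is not None else synthetic.CohortConfig()
    phantom_cfg = phantom_cfg if phantom_cfg is not None else synthetic.PhantomConfig()
    config = config if config is not None else PipelineConfig(seed=cohort_cfg.seed)

    slices, table, truths = synthetic.generate_cohort(cohort_cfg, phantom_cfg)
    feats = _extract_cohort_features(slices, table, config)
    results = analyze_cohort(feats, table, config)
    results.update({"table": table, "features": feats, "truths": truths})
    return results
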