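"""End-to-end orchestration: images -> cells -> positivity -> statistics.

One run consumes an image manifest (CSV mapping each field's DAPI and signal
TIFF/PNG to its experiment, arm, treatment and field index), derives one
positivity threshold per experiment from that experiment's untreated control,
scores and classifies every cell with it, computes treated-vs-untreated fold
changes per arm, screens the replicate fold changes with the Grubbs test and
compares arms with paired t-tests.  All intermediate tables are written to
the output directory together with a provenance manifest recording input
hashes, the exact thresholds and every parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.io import imread

from . import __version__
from .classify import (
    ExperimentThreshold,
    derive_threshold,
    count_positive,
    summarize_positivity,
)
from .score import CellTable, assign_max_signal
from .segment import SegmentationParams, segment_nuclei, subtract_background
from .simgen import MANIFEST_COLUMNS
from .stats import fold_change, grubbs_exclude, paired_t_test

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_image_manifest",
    "run_costress_pipeline",
    "quantify_image_pairs",
]

logger = logging.getLogger("gammahq")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on, serializable to JSON."""

    manifest_path: str
    outdir: str
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    signal_background_method: str | None = None  # defaults to the DAPI method
    signal_background_radius: int | None = None
    score_percentile: float = 100.0
    threshold_method: str = "mean_k_sd"
    threshold_params: dict = field(default_factory=dict)
    control_arm: str = "control"
    control_treatment: str = "untreated"
    per_arm_thresholds: bool = False
    alpha: float = 0.05
    arm_pooling: dict = field(default_factory=dict)  # e.g. {"nacl100": "osmotic"}
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @staticmethod
    def from_json(path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        seg = d.pop("segmentation", {})
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(segmentation=SegmentationParams(**seg), **d)


@dataclass
class PipelineResult:
    cells: CellTable
    thresholds: dict
    positivity: pd.DataFrame
    positivity_per_field: pd.DataFrame
    fold_changes: pd.DataFrame
    paired_tests: pd.DataFrame
    grubbs_audit: dict
    run_manifest: dict


def read_image_manifest(path) -> pd.DataFrame:
    """Load and validate an image manifest CSV, reporting all problems at once."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    problems = []
    dup = df.loc[df["image_id"].duplicated(), "image_id"]
    for image_id in dup:
        problems.append(f"duplicated image_id {image_id!r}")
    base = Path(path).parent
    for _, row in df.iterrows():
        for col in ("dapi_path", "signal_path"):
            p = Path(str(row[col]))
            if not p.is_absolute():
                p = base / p
            if not p.is_file():
                problems.append(f"{row['image_id']}: missing file {row[col]}")
    if problems:
        raise ValueError("invalid manifest: " + "; ".join(problems))
    return df


def _load_channel(path_str: str, base: Path) -> np.ndarray:
    p = Path(path_str)
    if not p.is_absolute():
        p = base / p
    try:
        img = imread(p)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"unreadable image {p}: {exc}") from exc
    if img.ndim != 2:
        raise ValueError(f"{p}: expected a single-channel 2-D image, got {img.shape}")
    return img


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def quantify_image_pairs(
    images,
    segmentation: SegmentationParams | None = None,
    signal_background_method: str | None = None,
    signal_background_radius: int | None = None,
    score_percentile: float = 100.0,
) -> CellTable:
    """Segment and score a collection of in-memory image pairs.

    The library-level counterpart of the file-based pipeline: for each
    :class:`~gammahq.simgen.FluorImagePair` the DAPI channel is segmented,
    the signal channel background-corrected (same method/radius as the DAPI
    unless overridden) and every cell scored by its brightest pixel.  Returns
    one pooled :class:`CellTable` carrying each image's condition metadata.
    """
    seg = segmentation or SegmentationParams()
    method = signal_background_method or seg.background_method
    radius = signal_background_radius or seg.background_radius
    tables = []
    for pair in images:
        labels = segment_nuclei(pair.dapi, seg)
        corrected = subtract_background(pair.signal, method, radius)
        tables.append(
            assign_max_signal(
                labels,
                corrected,
                image_id=pair.image_id,
                experiment=pair.experiment,
                arm=pair.arm,
                treatment=pair.treatment,
                field_index=pair.field_index,
                percentile=score_percentile,
            )
        )
    return CellTable.concat(tables)


def run_costress_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full quantification on every image listed in the manifest.

    Per experiment the positivity threshold is derived once, from the pooled
    cells of the untreated control condition (of ``control_arm`` by default;
    with ``per_arm_thresholds`` each arm is anchored to its own untreated
    condition), then applied to every image of that experiment.  Conditions
    that segment to zero cells are flagged and skipped rather than aborting
    the run.  The run is deterministic given the config and inputs; result
    CSVs are byte-identical across re-runs.
    """
    logging.basicConfig(level=config.log_level)
    manifest = read_image_manifest(config.manifest_path)
    if config.arm_pooling:
        manifest = manifest.assign(
            arm=manifest["arm"].map(lambda a: config.arm_pooling.get(a, a))
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(config.manifest_path).parent

    for exp, grp in manifest.groupby("experiment"):
        has_control = (
            (grp["treatment"] == config.control_treatment)
            & ((grp["arm"] == config.control_arm) | config.per_arm_thresholds)
        ).any()
        if not has_control:
            raise ValueError(
                f"experiment {exp!r} has no untreated control "
                f"({config.control_arm}/{config.control_treatment})"
            )

    sig_method = config.signal_background_method or config.segmentation.background_method
    sig_radius = config.signal_background_radius or config.segmentation.background_radius

    tables = []
    image_provenance = {}
    for _, row in manifest.iterrows():
        dapi = _load_channel(row["dapi_path"], base)
        signal = _load_channel(row["signal_path"], base)
        if dapi.shape != signal.shape:
            raise ValueError(f"{row['image_id']}: channel shape mismatch")
        labels = segment_nuclei(dapi, config.segmentation)
        corrected = subtract_background(signal, sig_method, sig_radius)
        table = assign_max_signal(
            labels,
            corrected,
            image_id=str(row["image_id"]),
            experiment=str(row["experiment"]),
            arm=str(row["arm"]),
            treatment=str(row["treatment"]),
            field_index=int(row["field"]),
            percentile=config.score_percentile,
        )
        if len(table) == 0:
            logger.warning("image %s segmented to zero cells", row["image_id"])
        tables.append(table)
        p = Path(str(row["dapi_path"]))
        image_provenance[str(row["image_id"])] = {
            "dapi_sha256": _sha256(p if p.is_absolute() else base / p),
            "signal_sha256": _sha256(
                Path(str(row["signal_path"]))
                if Path(str(row["signal_path"])).is_absolute()
                else base / str(row["signal_path"])
            ),
            "n_cells": len(table),
        }
    cells = CellTable.concat(tables)

    thresholds: dict[str, ExperimentThreshold] = {}
    positivity_rows = []
    per_field_rows = []
    fc_rows = []
    for exp, exp_df in cells.df.groupby("experiment"):
        exp_cells = CellTable(exp_df.reset_index(drop=True))
        arms = sorted(exp_df["arm"].unique())
        arm_groups = arms if config.per_arm_thresholds else [None]
        for arm_key in arm_groups:
            anchor_arm = arm_key if arm_key is not None else config.control_arm
            ctrl_mask = (exp_df["arm"] == anchor_arm) & (
                exp_df["treatment"] == config.control_treatment
            )
            ctrl = CellTable(exp_df[ctrl_mask].reset_index(drop=True))
            if len(ctrl) == 0:
                raise ValueError(
                    f"experiment {exp!r}: no segmented cells in the untreated "
                    f"control ({anchor_arm})"
                )
            thr = derive_threshold(
                ctrl, config.threshold_method, dict(config.threshold_params)
            )
            key = f"{exp}:{arm_key}" if arm_key is not None else str(exp)
            thresholds[key] = thr
            scope = (
                exp_cells
                if arm_key is None
                else CellTable(exp_df[exp_df["arm"] == arm_key].reset_index(drop=True))
            )
            positivity_rows.append(summarize_positivity(scope, thr))
            per_field_rows.append(summarize_positivity(scope, thr, per_field=True))
            for arm in sorted(scope.df["arm"].unique()):
                arm_df = scope.df[scope.df["arm"] == arm]
                untreated_df = arm_df[arm_df["treatment"] == config.control_treatment]
                if len(untreated_df) == 0:
                    logger.warning(
                        "experiment %s arm %s has no untreated condition; "
                        "fold changes skipped",
                        exp,
                        arm,
                    )
                    continue
                untreated = count_positive(
                    CellTable(untreated_df.reset_index(drop=True)), thr
                )
                for treatment in sorted(arm_df["treatment"].unique()):
                    if treatment == config.control_treatment:
                        continue
                    treated = count_positive(
                        CellTable(
                            arm_df[arm_df["treatment"] == treatment].reset_index(
                                drop=True
                            )
                        ),
                        thr,
                    )
                    fc = fold_change(treated, untreated)
                    fc_rows.append(
                        {
                            "experiment": fc.experiment,
                            "arm": fc.arm,
                            "treatment": fc.treatment,
                            "fc": fc.fc,
                            "undefined": fc.undefined,
                            "reason": fc.reason,
                        }
                    )

    positivity = pd.concat(positivity_rows, ignore_index=True)
    positivity_per_field = pd.concat(per_field_rows, ignore_index=True)
    fold_changes = pd.DataFrame(
        fc_rows, columns=["experiment", "arm", "treatment", "fc", "undefined", "reason"]
    )

    # replicate-level statistics: Grubbs screening per condition, then paired
    # t-tests comparing the control arm's fold changes with each other arm's,
    # paired by experiment
    grubbs_audit = {}
    usable = fold_changes[~fold_changes["undefined"]]
    retained = {}
    for (arm, treatment), grp in usable.groupby(["arm", "treatment"]):
        vals = grp["fc"].to_numpy(dtype=float)
        res = grubbs_exclude(vals, config.alpha)
        grubbs_audit[f"{arm}/{treatment}"] = {
            "values": list(res.values),
            "experiments": list(grp["experiment"]),
            "excluded_indices": list(res.excluded_indices),
            "g_statistics": list(res.g_statistics),
            "critical_values": list(res.critical_values),
            "alpha": res.alpha,
        }
        kept = [i for i in range(len(vals)) if i not in res.excluded_indices]
        retained[(arm, treatment)] = dict(
            zip(grp["experiment"].iloc[kept], vals[kept])
        )

    test_rows = []
    other_arms = sorted(
        {a for a, _ in retained if a != config.control_arm}
    )
    treatments = sorted({t for _, t in retained})
    for other in other_arms:
        for treatment in treatments:
            ctrl_fc = retained.get((config.control_arm, treatment), {})
            osmo_fc = retained.get((other, treatment), {})
            common = sorted(set(ctrl_fc) & set(osmo_fc))
            if len(common) < 2:
                logger.warning(
                    "treatment %s: fewer than 2 paired experiments for arms "
                    "%s vs %s; paired test skipped",
                    treatment,
                    config.control_arm,
                    other,
                )
                continue
            res = paired_t_test(
                [ctrl_fc[e] for e in common], [osmo_fc[e] for e in common]
            )
            test_rows.append(
                {
                    "treatment": treatment,
                    "arm_a": config.control_arm,
                    "arm_b": other,
                    "n_pairs": res.n_pairs,
                    "t_statistic": res.t_statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "normality_w": res.normality_w,
                    "normality_p": res.normality_p,
                    "degenerate": res.degenerate,
                }
            )
    paired_tests = pd.DataFrame(
        test_rows,
        columns=[
            "treatment",
            "arm_a",
            "arm_b",
            "n_pairs",
            "t_statistic",
            "df",
            "p_value",
            "normality_w",
            "normality_p",
            "degenerate",
        ],
    )

    run_manifest = {
        "software": "gammahq",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "thresholds": {k: asdict(t) for k, t in thresholds.items()},
        "images": image_provenance,
    }

    cells.to_csv(outdir / "cells.csv")
    positivity.to_csv(outdir / "positivity.csv", index=False)
    positivity_per_field.to_csv(outdir / "positivity_per_field.csv", index=False)
    fold_changes.to_csv(outdir / "fold_changes.csv", index=False)
    paired_tests.to_csv(outdir / "paired_tests.csv", index=False)
    for key, thr in thresholds.items():
        thr.to_json(outdir / f"threshold_{key.replace(':', '_')}.json")
    with open(outdir / "grubbs_audit.json", "w") as fh:
        json.dump(grubbs_audit, fh, indent=2)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)

    return PipelineResult(
        cells=cells,
        thresholds=thresholds,
        positivity=positivity,
        positivity_per_field=positivity_per_field,
        fold_changes=fold_changes,
        paired_tests=paired_tests,
        grubbs_audit=grubbs_audit,
        run_manifest=run_manifest,
    )
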