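"""Control-anchored positivity classification.

One intensity threshold is derived from the untreated control of an
experiment and reused, unchanged, for every other image of that experiment.
A cell is gamma-H2AX-positive when its per-cell maximum signal strictly
exceeds the threshold; percent-positive is reported per condition with cells
pooled across fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .score import CellTable

__all__ = [
    "ExperimentThreshold",
    "PositivitySummary",
    "derive_threshold",
    "count_positive",
    "summarize_positivity",
]

THRESHOLD_METHODS = ("mean_k_sd", "percentile", "otsu_on_scores", "fixed")


@dataclass(frozen=True)
class ExperimentThreshold:
    """Single positivity cutoff for one experiment, with provenance."""

    experiment: str
    threshold: float
    method: str
    method_params: dict = field(default_factory=dict)
    source_condition: tuple[str, str] = ("control", "untreated")
    n_control_cells: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @staticmethod
    def from_json(path) -> "ExperimentThreshold":
        with open(path) as fh:
            d = json.load(fh)
        d["source_condition"] = tuple(d["source_condition"])
        return ExperimentThreshold(**d)


@dataclass(frozen=True)
class PositivitySummary:
    experiment: str
    arm: str
    treatment: str
    n_cells: int
    n_positive: int
    threshold: float = math.nan

    @property
    def pct_positive(self) -> float:
        """Percent positive; NaN (flagged undefined) when no cells were seen."""
        if self.n_cells == 0:
            return math.nan
        return 100.0 * self.n_positive / self.n_cells


def derive_threshold(
    control_cells: CellTable,
    method: str = "mean_k_sd",
    method_params: dict | None = None,
    experiment: str | None = None,
) -> ExperimentThreshold:
    """Derive the experiment's positivity cutoff from its untreated control.

    Methods
    -------
    mean_k_sd   mean + k * sd (sample sd) of the control per-cell max signals;
                k defaults to 2.  The default control-anchored rule.
    percentile  the p-th percentile (linear interpolation), p default 95.
    otsu_on_scores  Otsu's threshold on the 1-D score distribution.
    fixed       a user-supplied value, ignoring the data.
    """
    params = dict(method_params or {})
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method {method!r}")
    if len(control_cells) == 0 and method != "fixed":
        raise ValueError("cannot derive a threshold from an empty control table")
    if experiment is None:
        exps = control_cells.df["experiment"].unique()
        if len(exps) != 1:
            raise ValueError(
                f"control table spans {len(exps)} experiments; pass experiment="
            )
        experiment = str(exps[0])
    scores = control_cells.max_signals
    if method == "mean_k_sd":
        k = float(params.setdefault("k", 2.0))
        sd = scores.std(ddof=1) if scores.size > 1 else 0.0
        thr = float(scores.mean() + k * sd)
    elif method == "percentile":
        p = float(params.setdefault("p", 95.0))
        thr = float(np.percentile(scores, p))
    elif method == "otsu_on_scores":
        thr = float(threshold_otsu(scores))
    else:  # fixed
        if "value" not in params:
            raise ValueError("fixed threshold requires method_params['value']")
        thr = float(params["value"])
    if not math.isfinite(thr) or thr < 0:
        raise ValueError(f"derived threshold {thr} is not finite and >= 0")
    source = ("control", "untreated")
    if len(control_cells):
        arms = control_cells.df["arm"].unique()
        treatments = control_cells.df["treatment"].unique()
        if len(arms) == 1 and len(treatments) == 1:
            source = (str(arms[0]), str(treatments[0]))
    return ExperimentThreshold(
        experiment=experiment,
        threshold=thr,
        method=method,
        method_params=params,
        source_condition=source,
        n_control_cells=len(control_cells),
    )


def count_positive(
    cells: CellTable, threshold: ExperimentThreshold
) -> PositivitySummary:
    """Pool one condition's cells and count those above the cutoff.

    Positivity is a strict inequality: a score exactly at the threshold is
    negative.  All rows must belong to the threshold's experiment and to a
    single (arm, treatment) condition; pooling across fields is implicit.
    """
    df = cells.df
    if len(df) == 0:
        raise ValueError("empty cell table; condition identity is ambiguous")
    exps = df["experiment"].unique()
    if len(exps) != 1 or str(exps[0]) != threshold.experiment:
        raise ValueError(
            f"cells belong to {list(exps)} but threshold is for "
            f"{threshold.experiment!r}"
        )
    arms = df["arm"].unique()
    treatments = df["treatment"].unique()
    if len(arms) != 1 or len(treatments) != 1:
        raise ValueError("count_positive expects a single (arm, treatment) condition")
    scores = cells.max_signals
    n_pos = int((scores > threshold.threshold).sum())
    return PositivitySummary(
        experiment=threshold.experiment,
        arm=str(arms[0]),
        treatment=str(treatments[0]),
        n_cells=int(scores.size),
        n_positive=n_pos,
        threshold=threshold.threshold,
    )


def summarize_positivity(
    cells: CellTable, threshold: ExperimentThreshold, per_field: bool = False
) -> pd.DataFrame:
    """Percent positive per condition (or per field) of one experiment.

    Returns one row per (arm, treatment) with cells pooled over fields, or,
    with ``per_field``, one row per (arm, treatment, field) for use by the
    replicate-level statistics.
    """
    keys = ["arm", "treatment"] + (["field"] if per_field else [])
    rows = []
    for key, grp in cells.df.groupby(keys, sort=True):
        scores = grp["max_signal"].to_numpy(dtype=float)
        n_pos = int((scores > threshold.threshold).sum())
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            experiment=threshold.experiment,
            n_cells=int(scores.size),
            n_positive=n_pos,
            pct_positive=100.0 * n_pos / scores.size,
            threshold=threshold.threshold,
        )
        rows.append(row)
    cols = ["experiment", *keys, "n_cells", "n_positive", "pct_positive", "threshold"]
    return pd.DataFrame(rows, columns=cols)
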