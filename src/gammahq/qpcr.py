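"""Relative quantification of TaqMan qPCR data by the 2^-ddCt method.

Cq values are normalized per sample to a reference gene (18S in the source
assays): dCt = Cq(target) - Cq(reference), with technical replicates averaged
at the Cq level first.  ddCt is the difference of condition means of dCt
(treated minus control), and the fold change is 2^-ddCt, assuming perfect
doubling per cycle.  Outlying dCt values are screened per gene and condition
with the iterated Grubbs test before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import grubbs_exclude

__all__ = [
    "CQ_COLUMNS",
    "DdctResult",
    "read_cq_table",
    "validate_cq_table",
    "delta_ct",
    "sample_delta_ct",
    "ddct_fold_change",
    "analyze_qpcr",
]

CQ_COLUMNS = ["sample_id", "condition", "gene", "replicate", "cq"]


@dataclass(frozen=True)
class DdctResult:
    gene: str
    delta_ct_control: float
    delta_ct_treated: float
    ddct: float
    fold_change: float
    log2_fc: float
    n_used: int
    excluded: tuple[float, ...] = ()


def validate_cq_table(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Check the Cq table schema and invariants, reporting all problems at once."""
    problems = []
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    cq = pd.to_numeric(table["cq"], errors="coerce")
    bad = table.index[~np.isfinite(cq) | (cq <= 0)]
    if len(bad):
        problems.append(f"non-finite or non-positive cq in rows {list(bad)}")
    for sample_id, grp in table.groupby("sample_id"):
        if reference_gene not in set(grp["gene"]):
            problems.append(
                f"sample {sample_id!r} has no reference gene {reference_gene!r}"
            )
    if problems:
        raise ValueError("invalid Cq table: " + "; ".join(problems))
    return table


def read_cq_table(path, reference_gene: str = "18S") -> pd.DataFrame:
    return validate_cq_table(pd.read_csv(path), reference_gene)


def delta_ct(cq_target: float, cq_reference: float) -> float:
    """Reference-normalized Cq: Cq(target) minus Cq(reference gene)."""
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return cq_target - cq_reference


def sample_delta_ct(
    table: pd.DataFrame, gene: str, reference_gene: str, condition: str
) -> list[float]:
    """Per-sample dCt for one gene and condition.

    Technical replicates are averaged at the Cq level for both the target and
    the reference gene before subtraction.
    """
    sub = table[table["condition"] == condition]
    out = []
    for sample_id, grp in sub.groupby("sample_id", sort=True):
        target = grp.loc[grp["gene"] == gene, "cq"]
        ref = grp.loc[grp["gene"] == reference_gene, "cq"]
        if target.empty:
            continue
        if ref.empty:
            raise ValueError(
                f"sample {sample_id!r} lacks reference gene {reference_gene!r}"
            )
        out.append(delta_ct(float(target.mean()), float(ref.mean())))
    return out


def ddct_fold_change(
    delta_ct_treated_values,
    delta_ct_control_values,
    alpha: float = 0.05,
    gene: str = "",
) -> DdctResult:
    """ddCt and 2^-ddCt from per-sample dCt lists, with Grubbs screening.

    Each condition's dCt list is screened independently; ddCt is the
    difference of the retained means.  A negative true log2 fold change
    (downregulation) raises the treated dCt and yields a fold change < 1.
    """
    treated = list(map(float, delta_ct_treated_values))
    control = list(map(float, delta_ct_control_values))
    if not treated or not control:
        raise ValueError("both dCt lists must be non-empty")
    g_treated = grubbs_exclude(treated, alpha)
    g_control = grubbs_exclude(control, alpha)
    kept_t = g_treated.retained
    kept_c = g_control.retained
    if not kept_t or not kept_c:
        raise ValueError("all dCt values excluded as outliers")
    excluded = tuple(treated[i] for i in g_treated.excluded_indices) + tuple(
        control[i] for i in g_control.excluded_indices
    )
    dct_t = float(np.mean(kept_t))
    dct_c = float(np.mean(kept_c))
    ddct = dct_t - dct_c
    return DdctResult(
        gene=gene,
        delta_ct_control=dct_c,
        delta_ct_treated=dct_t,
        ddct=ddct,
        fold_change=2.0**-ddct,
        log2_fc=-ddct,
        n_used=len(kept_t) + len(kept_c),
        excluded=excluded,
    )


def analyze_qpcr(
    table: pd.DataFrame, reference_gene: str = "18S", alpha: float = 0.05
) -> pd.DataFrame:
    """Run the full ddCt analysis for every target gene in a Cq table."""
    validate_cq_table(table, reference_gene)
    genes = sorted(g for g in table["gene"].unique() if g != reference_gene)
    rows = []
    for gene in genes:
        dct_c = sample_delta_ct(table, gene, reference_gene, "control")
        dct_t = sample_delta_ct(table, gene, reference_gene, "treated")
        res = ddct_fold_change(dct_t, dct_c, alpha=alpha, gene=gene)
        rows.append(
            {
                "gene": res.gene,
                "delta_ct_control": res.delta_ct_control,
                "delta_ct_treated": res.delta_ct_treated,
                "ddct": res.ddct,
                "fold_change": res.fold_change,
                "log2_fc": res.log2_fc,
                "n_used": res.n_used,
                "n_excluded": len(res.excluded),
            }
        )
    return pd.DataFrame(rows)
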