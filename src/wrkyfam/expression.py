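"""Relative expression from qPCR quantification-cycle (Cq) tables.

Implements the comparative-Ct method: within each (gene, condition,
timepoint) group, technical-replicate Cq values are averaged on the cycle
scale for the target and for the reference gene; dCt = Cq_target -
Cq_reference; ddCt = dCt_treated - dCt_control; fold change = 2^-ddCt.
A fold change above 1 means up-regulation, below 1 down-regulation; a small
tolerance band around 1 (default +/-5%) yields an "unchanged" call, since a
hard 1.0 cutoff is numerically fragile.  Missing treated groups are
reported as "undetected" rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

CQ_COLUMNS = [
    "gene_id", "condition", "timepoint", "replicate", "cq_target", "cq_reference",
]
CONTROL_CONDITION = "control"
DEFAULT_EPSILON = 0.05


@dataclass
class RelativeExpression:
    gene_id: str
    condition: str
    timepoint: str
    fold_change: Optional[float]  # None when undetected
    call: str  # up | down | unchanged | undetected


def read_cq_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[(df.cq_target <= 0) | (df.cq_target >= 45)
             | (df.cq_reference <= 0) | (df.cq_reference >= 45)]
    if len(bad):
        raise ValueError(f"{path}: Cq values outside (0, 45) in {len(bad)} rows")
    return df


def delta_ct(group: pd.DataFrame) -> float:
    """Replicate-mean Cq difference (target minus reference) for one group."""
    if group.empty:
        raise ValueError("empty Cq group")
    return float(group["cq_target"].mean() - group["cq_reference"].mean())


def delta_delta_ct(treated: pd.DataFrame, control: pd.DataFrame) -> float:
    if control.empty:
        raise ValueError("missing control group")
    if treated.empty:
        raise ValueError("missing treated group")
    return delta_ct(treated) - delta_ct(control)


def fold_change(ddct: float, epsilon: float = DEFAULT_EPSILON) -> tuple[float, str]:
    """2^-ddCt and its regulation call."""
    if not math.isfinite(ddct):
        raise ValueError(f"non-finite ddCt: {ddct}")
    fc = 2.0 ** (-ddct)
    if fc > 1.0 + epsilon:
        call = "up"
    elif fc < 1.0 - epsilon:
        call = "down"
    else:
        call = "unchanged"
    return fc, call


def expression_matrix(
    records: pd.DataFrame, epsilon: float = DEFAULT_EPSILON
) -> list[RelativeExpression]:
    """Fold change for every (gene, non-control condition, timepoint) cell.

    A control group must exist for every (gene, timepoint); treated groups
    that are absent from the table yield an ``undetected`` cell.
    """
    df = records
    conditions = [c for c in df["condition"].unique() if c != CONTROL_CONDITION]
    out = []
    for gene_id, gene_df in df.groupby("gene_id", sort=True):
        for timepoint in sorted(gene_df["timepoint"].unique()):
            tp_df = gene_df[gene_df["timepoint"] == timepoint]
            control = tp_df[tp_df["condition"] == CONTROL_CONDITION]
            if control.empty:
                raise ValueError(
                    f"{gene_id} @ {timepoint}: no control measurements"
                )
            for condition in conditions:
                treated = tp_df[tp_df["condition"] == condition]
                if treated.empty:
                    out.append(
                        RelativeExpression(gene_id, condition, timepoint, None,
                                           "undetected")
                    )
                    continue
                fc, call = fold_change(delta_delta_ct(treated, control), epsilon)
                out.append(
                    RelativeExpression(gene_id, condition, timepoint, fc, call)
                )
    return out


def expression_table(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    """Long-form DataFrame of fold changes and calls (TSV-ready)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "condition": [r.condition for r in results],
            "timepoint": [r.timepoint for r in results],
            "fold_change": [r.fold_change for r in results],
            "call": [r.call for r in results],
        }
    )
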