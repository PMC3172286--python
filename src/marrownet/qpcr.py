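"""Relative quantification of qPCR data by the 2^-ddCt method.

For each replicate, dCt = Ct(target) - Ct(reference); the double delta
ddCt = mean dCt(treated) - mean dCt(control) gives the fold change
2^-ddCt (Livak aggregation: means of dCt first, one fold per condition
pair). The spread is reported as the standard deviation of per-replicate
folds, each computed against the control mean dCt. Amplification
efficiency is fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DifferentialTable

__all__ = ["FoldChangeResult", "ddct_fold", "ddct_table", "concordance"]

log = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    timepoint_days: int
    fold: float
    sd: float
    n_treated: int
    n_control: int

    @property
    def log2_fold(self) -> float:
        return float(np.log2(self.fold))


def _delta_ct(rows: pd.DataFrame) -> np.ndarray:
    return (rows["ct_target"] - rows["ct_reference"]).to_numpy(dtype=float)


def ddct_fold(ct_table: pd.DataFrame, gene: str, timepoint_days: int) -> FoldChangeResult:
    """Fold change of one gene at one timepoint relative to control.

    The control rows are those with condition == 'control' for the gene
    (shared across timepoints); treated rows are condition == 'treated'
    at the requested timepoint.
    """
    rows = ct_table[ct_table["gene"] == gene]
    control = rows[rows["condition"] == CONTROL]
    treated = rows[(rows["condition"] == TREATED) & (rows["timepoint_days"] == timepoint_days)]
    if control.empty or treated.empty:
        missing = CONTROL if control.empty else f"{TREATED}@{timepoint_days}"
        raise ValueError(f"no {missing} Ct records for gene {gene!r} at t={timepoint_days}")
    dct_control = _delta_ct(control)
    dct_treated = _delta_ct(treated)
    ddct = dct_treated.mean() - dct_control.mean()
    fold = float(2.0 ** (-ddct))
    per_replicate = 2.0 ** (-(dct_treated - dct_control.mean()))
    sd = float(per_replicate.std(ddof=1)) if per_replicate.size > 1 else 0.0
    return FoldChangeResult(
        gene=gene,
        timepoint_days=int(timepoint_days),
        fold=fold,
        sd=sd,
        n_treated=len(treated),
        n_control=len(control),
    )


def ddct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Fold changes for every (gene, treated timepoint) in the Ct table."""
    rows = []
    treated = ct_table[ct_table["condition"] == TREATED]
    for gene, tp in sorted(
        {(r.gene, int(r.timepoint_days)) for r in treated.itertuples(index=False)}
    ):
        res = ddct_fold(ct_table, gene, tp)
        rows.append(
            {
                "gene": gene,
                "timepoint_days": tp,
                "fold": res.fold,
                "log2_fold": res.log2_fold,
                "sd": res.sd,
                "n_treated": res.n_treated,
                "n_control": res.n_control,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "timepoint_days", "fold", "log2_fold", "sd", "n_treated", "n_control"],
    )


def concordance(array_table: DifferentialTable, qpcr_folds: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Direction agreement between array and qPCR fold changes.

    Compares sign(log2 array fold change) with sign(log2 qPCR fold) for
    every shared (gene, timepoint); returns the per-pair table and the
    overall concordant fraction. Symbols are matched case-insensitively.
    """
    array = array_table.table.copy()
    array["gene_uc"] = array["gene"].str.upper()
    qpcr = qpcr_folds.copy()
    qpcr["gene_uc"] = qpcr["gene"].str.upper()
    merged = array.merge(
        qpcr, on=["gene_uc", "timepoint_days"], suffixes=("_array", "_qpcr")
    )
    if merged.empty:
        raise ValueError("array and qPCR tables share no (gene, timepoint) keys")
    merged["concordant"] = np.sign(merged["log2_fold_change"]) == np.sign(
        merged["log2_fold"]
    )
    out = merged[
        ["gene_uc", "timepoint_days", "log2_fold_change", "log2_fold", "concordant"]
    ].rename(columns={"gene_uc": "gene", "log2_fold": "log2_fold_qpcr"})
    return out, float(out["concordant"].mean())
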