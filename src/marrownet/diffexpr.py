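"""Per-timepoint differential expression against the sham baseline.

Each post-baseline timepoint is compared to the baseline group with an
unequal-variance (Welch) two-sample t-test on log2 intensities; the
pooled-variance Student test is available via ``equal_var=True``. A gene
is flagged differential when its raw p falls below ``alpha`` at one or
more timepoints; Benjamini-Hochberg q-values across genes are reported
alongside for each timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = ["welch_t", "bh_fdr", "call_differential", "DifferentialTable"]

log = logging.getLogger(__name__)


def welch_t(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch-Satterthwaite df by default.

    Degenerate inputs (zero variance in both groups) follow the
    convention p=1 for equal means and p=0 for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values for a t-test")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            log.debug("both groups constant and equal; p = 1 by convention")
            return 0.0, 1.0
        log.debug("both groups constant but unequal; p = 0 by convention")
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DifferentialTable:
    """Differential-expression results.

    ``table`` is long-format: gene, timepoint_days, log2_fold_change,
    p_value, q_value (q computed per timepoint across genes).
    ``significant_any`` is a per-gene flag: p < alpha at >= 1 timepoint.
    """

    table: pd.DataFrame
    significant_any: pd.Series
    alpha: float

    def significant_genes(self) -> list[str]:
        return list(self.significant_any.index[self.significant_any])

    def genes(self) -> list[str]:
        return list(self.significant_any.index)

    def fold_changes(self) -> pd.DataFrame:
        """Wide genes x timepoints log2 fold-change matrix."""
        return self.table.pivot(
            index="gene", columns="timepoint_days", values="log2_fold_change"
        ).loc[self.genes()]

    def to_wide(self) -> pd.DataFrame:
        wide = self.table.pivot(
            index="gene",
            columns="timepoint_days",
            values=["log2_fold_change", "p_value", "q_value"],
        )
        wide.columns = [f"{stat}_t{tp}" for stat, tp in wide.columns]
        wide = wide.loc[self.genes()]
        wide["significant_any"] = self.significant_any
        return wide

    def write(self, path: str | Path) -> None:
        out = self.to_wide()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def call_differential(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    equal_var: bool = False,
    baseline_pooled: bool = False,
) -> DifferentialTable:
    """Test every gene at every post-baseline timepoint against baseline.

    Tests run on log2 intensities; log2_fold_change is the timepoint mean
    minus the baseline mean. ``baseline_pooled`` pools every chip whose
    metadata group is baseline (for designs with a single sham chip per
    timepoint); otherwise the baseline is the timepoint-0 group and must
    have >= 2 replicates.
    """
    log2 = matrix.log2()
    baseline_ids = matrix.baseline_samples(pooled=baseline_pooled)
    if len(baseline_ids) < 2:
        raise ValueError(
            f"baseline has {len(baseline_ids)} replicate(s); >= 2 required "
            "(use baseline_pooled to pool sham chips across timepoints)"
        )
    base = log2[baseline_ids].to_numpy()
    timepoints = [t for t in matrix.timepoints if t != 0]
    if not timepoints:
        raise ValueError("matrix has no post-baseline timepoints")

    frames = []
    for tp in timepoints:
        ids = matrix.samples_at(tp)
        ids = [s for s in ids if s not in baseline_ids]
        if len(ids) < 2:
            raise ValueError(f"timepoint {tp} has {len(ids)} replicate(s); >= 2 required")
        grp = log2[ids].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(grp, base, axis=1, equal_var=equal_var)
        p = np.asarray(p, dtype=float)
        # degenerate rows: zero variance in both groups
        degenerate = (grp.var(axis=1, ddof=1) == 0) & (base.var(axis=1, ddof=1) == 0)
        if degenerate.any():
            equal = degenerate & (grp.mean(axis=1) == base.mean(axis=1))
            p[equal] = 1.0
            p[degenerate & ~equal] = 0.0
            log.info("%d gene(s) with zero variance in both groups at t=%d",
                     int(degenerate.sum()), tp)
        lfc = grp.mean(axis=1) - base.mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene": matrix.genes,
                    "timepoint_days": tp,
                    "log2_fold_change": lfc,
                    "p_value": p,
                    "q_value": bh_fdr(p),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    sig = (
        table.assign(hit=table["p_value"] < alpha)
        .groupby("gene", sort=False)["hit"]
        .any()
        .loc[matrix.genes]
    )
    sig.name = "significant_any"
    return DifferentialTable(table=table, significant_any=sig, alpha=alpha)
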