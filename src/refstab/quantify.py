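"""Relative quantification by 2^-ddCq with multi-reference normalization.

A target's Cq is normalized per sample against the arithmetic mean Cq of
one or more reference genes (equivalent to the geometric mean of their
quantities under perfect doubling), calibrated to a designated control
group's mean dCq, and expressed as a fold change 2^-ddCq.  Group
differences are tested with one-way ANOVA followed by Tukey's multiple
comparison test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CqDataset


@dataclass
class RelativeExpression:
    fold_change: pd.Series          # per sample, 2^-ddCq
    delta_cq: pd.Series             # per sample, Cq_target - mean(Cq_refs)
    target: str
    references: list[str]
    calibrator_group: str
    groups: pd.Series               # per sample group label

    def by_group(self) -> dict[str, pd.Series]:
        return {
            g: self.fold_change[self.groups == g]
            for g in dict.fromkeys(self.groups)
        }


@dataclass
class GroupTestReport:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    pairwise: pd.DataFrame          # Tukey-adjusted p per group pair
    posthoc_indicated: bool
    degenerate: bool = False
    scale: str = "fold_change"


def relative_expression(
    ds: CqDataset,
    target: str,
    references: Sequence[str],
    calibrator_group: str,
) -> RelativeExpression:
    """Per-sample fold changes of ``target`` relative to the calibrator group.

    dCq[s] = Cq_target[s] - mean_r(Cq_r[s]); ddCq subtracts the calibrator
    samples' mean dCq; fold change = 2^-ddCq, so the calibrator group's
    geometric-mean fold change is 1 by construction.
    """
    if not references:
        raise ValueError("at least one reference gene is required")
    missing_genes = [g for g in (target, *references) if g not in ds.genes]
    if missing_genes:
        raise KeyError(f"genes not in dataset: {missing_genes}")
    cols = [ds.gene_index(g) for g in (target, *references)]
    block = ds.cq[:, cols]
    if np.isnan(block).any():
        cells = [
            (ds.samples[i], [target, *references][j])
            for i, j in zip(*np.nonzero(np.isnan(block)))
        ]
        raise ValueError(f"missing Cq for required cells: {cells}")

    groups = pd.Series(ds.group_vector(), index=ds.samples, name="group")
    if not (groups == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")

    ref_mean = block[:, 1:].mean(axis=1)
    dcq = block[:, 0] - ref_mean
    ddcq = dcq - dcq[(groups == calibrator_group).to_numpy()].mean()
    fold = np.power(2.0, -ddcq)
    return RelativeExpression(
        fold_change=pd.Series(fold, index=ds.samples, name="fold_change"),
        delta_cq=pd.Series(dcq, index=ds.samples, name="delta_cq"),
        target=target,
        references=list(references),
        calibrator_group=calibrator_group,
        groups=groups,
    )


def anova_tukey(
    expr: RelativeExpression,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> GroupTestReport:
    """One-way ANOVA across groups, with Tukey HSD pairwise comparisons.

    Runs on linear fold changes by default (the conventional ddCq
    presentation); ``log_scale=True`` analyses log2 fold changes, which
    better matches ANOVA's homoscedasticity assumption.  Tukey p-values are
    always computed, with ``posthoc_indicated`` recording whether the
    overall p cleared ``alpha``.
    """
    values = np.log2(expr.fold_change) if log_scale else expr.fold_change
    group_order = list(dict.fromkeys(expr.groups))
    if len(group_order) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [values[expr.groups == g].to_numpy() for g in group_order]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 samples")
    n_total = sum(a.size for a in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))

    pooled = np.concatenate(arrays)
    if all(np.ptp(a) == 0 for a in arrays):
        pairs = _pair_frame(group_order, np.nan)
        return GroupTestReport(
            0.0, df, 1.0, pairs, posthoc_indicated=False, degenerate=True,
            scale="log2_fold_change" if log_scale else "fold_change",
        )

    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": group_order[i],
                    "group_b": group_order[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": float(tk.pvalue[i, j]),
                }
            )
    return GroupTestReport(
        f_statistic=float(f),
        df=df,
        p_value=float(p),
        pairwise=pd.DataFrame(rows),
        posthoc_indicated=bool(p < alpha),
        scale="log2_fold_change" if log_scale else "fold_change",
    )


def _pair_frame(groups: list[str], fill: float) -> pd.DataFrame:
    rows = [
        {"group_a": a, "group_b": b, "mean_diff": 0.0, "p_adj": fill}
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
    ]
    return pd.DataFrame(rows)
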