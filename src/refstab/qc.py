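"""Technical-replicate aggregation and admissibility QC.

Duplicate wells are averaged into one Cq per (sample, gene), and the
duplicate standard deviation is screened against the resolution limit for
detecting a two-fold expression change (SD <= 0.167 cycles).  Genes whose
tissue-level duplicate variability exceeds the cutoff are flagged for
exclusion, with an explicit per-gene override for judgment calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CqDataset

#: Duplicate-SD admissibility cutoff (cycles): the largest technical SD that
#: still resolves a 2-fold change in ~99.7% of cases.
DUPLICATE_SD_CUTOFF = 0.167


@dataclass
class ReplicateQCReport:
    """Per-pair and per-gene duplicate variability for one dataset."""

    tissue: str
    #: (sample, gene) -> duplicate SD (n-1 denominator); NaN if undefined.
    pair_sd: pd.DataFrame
    #: gene -> summary of per-sample duplicate SDs (mean by default).
    gene_summary: pd.Series
    #: (sample, gene) pairs with a single surviving replicate.
    single_replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    summary_statistic: str = "mean"

    def flagged_pairs(self, sd_cutoff: float = DUPLICATE_SD_CUTOFF) -> list[tuple[str, str]]:
        """Pairs whose duplicate SD exceeds the cutoff."""
        out = []
        for s in self.pair_sd.index:
            for g in self.pair_sd.columns:
                v = self.pair_sd.loc[s, g]
                if np.isfinite(v) and v > sd_cutoff:
                    out.append((s, g))
        return out


def aggregate_technical_replicates(
    ds: CqDataset, summary: str = "mean"
) -> tuple[CqDataset, ReplicateQCReport]:
    """Collapse technical replicates into mean Cq values.

    Returns the aggregated dataset (``cq`` = replicate arithmetic mean,
    ``replicate_cq`` dropped) and a QC report with the per-pair duplicate SD
    (sample SD, n-1 denominator) and a per-gene tissue-level summary.

    A dataset without stored replicates passes through unchanged, with an
    all-NaN report.  A (sample, gene) cell with a single surviving replicate
    keeps that value as its mean; its pair SD is undefined and excluded from
    the gene summary rather than counted as zero variability.
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    if ds.replicate_cq is None:
        pair = pd.DataFrame(np.nan, index=ds.samples, columns=ds.genes)
        gene = pd.Series(np.nan, index=ds.genes)
        report = ReplicateQCReport(ds.tissue, pair, gene, summary_statistic=summary)
        return ds, report

    rep = ds.replicate_cq
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(rep, axis=2)
        n_rep = np.sum(~np.isnan(rep), axis=2)
        sds = np.nanstd(rep, axis=2, ddof=1)
    sds[n_rep < 2] = np.nan

    singles = [
        (ds.samples[i], ds.genes[j])
        for i, j in zip(*np.nonzero(n_rep == 1))
    ]
    pair = pd.DataFrame(sds, index=ds.samples, columns=ds.genes)
    agg = summary if summary == "mean" else "median"
    with np.errstate(invalid="ignore"):
        gene = getattr(pair, agg)(axis=0, skipna=True)

    out = CqDataset(
        samples=list(ds.samples),
        genes=list(ds.genes),
        cq=means,
        groups=dict(ds.groups),
        tissue=ds.tissue,
        setting=ds.setting,
        replicate_cq=None,
    )
    report = ReplicateQCReport(
        ds.tissue, pair, gene, single_replicate_pairs=singles, summary_statistic=summary
    )
    return out, report


@dataclass
class ExclusionDecision:
    gene: str
    tissue: str
    summary_sd: float
    excluded: bool
    reason: str


def flag_high_variability_candidates(
    report: ReplicateQCReport,
    ds: CqDataset,
    sd_cutoff: float = DUPLICATE_SD_CUTOFF,
    keep: Iterable[str] = (),
) -> list[ExclusionDecision]:
    """Decide per-gene exclusion from the tissue-level duplicate-SD summary.

    A gene is excluded when its summary duplicate SD (mean of per-sample SDs
    by default) exceeds ``sd_cutoff``.  Genes listed in ``keep`` are retained
    despite the flag — the report records the override so the judgment call
    stays visible.
    """
    keep = set(keep)
    decisions: list[ExclusionDecision] = []
    for g in ds.genes:
        sd = float(report.gene_summary.get(g, np.nan))
        over = np.isfinite(sd) and sd > sd_cutoff
        if over and g in keep:
            decisions.append(ExclusionDecision(
                g, ds.tissue, sd, False,
                f"summary duplicate SD {sd:.3f} > {sd_cutoff} but kept by override",
            ))
        elif over:
            decisions.append(ExclusionDecision(
                g, ds.tissue, sd, True,
                f"summary duplicate SD {sd:.3f} > {sd_cutoff}",
            ))
        else:
            decisions.append(ExclusionDecision(g, ds.tissue, sd, False, "pass"))
    return decisions


def apply_exclusions(ds: CqDataset, decisions: Sequence[ExclusionDecision]) -> CqDataset:
    """Drop excluded genes from the dataset."""
    excluded = {d.gene for d in decisions if d.excluded}
    return ds.subset_genes([g for g in ds.genes if g not in excluded])


def correlate_qc_metrics(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between two per-sample QC metrics.

    Used e.g. to relate RNA integrity numbers to amplification efficiency.
    Returns ``(r, p)`` with a two-sided p-value from the t transform; when
    either metric has zero variance the correlation is undefined and
    ``(nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metrics must be paired 1-D sequences")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
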