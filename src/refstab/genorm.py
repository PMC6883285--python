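"""geNorm stability: M values, stepwise exclusion and pairwise variation V.

For each candidate, the expression stability M is the average standard
deviation of its log2 expression ratios against every other candidate.
With amplification efficiency assumed to be 2, the log2 ratio of genes
(g, h) in sample s is simply Cq[s,h] - Cq[s,g], so M coincides with the
comparative delta-Cq mean SD; per-amplicon efficiencies can be supplied to
work on efficiency-corrected relative quantities instead.

The least stable gene (largest M) is removed and M recomputed until two
genes remain — geNorm cannot order the final pair, which is reported as
tied at rank 1.5.  The pairwise-variation series V(n/n+1) — the SD of the
log2 ratio between normalization factors built from the n and n+1 best
genes — determines how many reference genes are needed: the smallest n
with V < 0.15 (default cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import CqDataset

V_CUTOFF_DEFAULT = 0.15
M_WARNING_THRESHOLD = 1.5


@dataclass
class GeNormResult:
    initial_m: pd.Series              # M with the full gene set
    exclusion_order: list[str]        # worst-first
    final_pair: tuple[str, str]
    m_trajectory: list[float]         # average M of remaining genes per step
    rank: pd.Series                   # final pair 1.5 each; excluded n, n-1, ...
    v_series: pd.Series               # index n, value V(n/n+1)
    optimal_n: int
    m_warnings: list[str] = field(default_factory=list)  # genes with M > 1.5
    tie_events: list[str] = field(default_factory=list)

    def ranking(self) -> list[str]:
        """Genes ordered best first (final pair first, by tie-break order)."""
        return list(self.rank.sort_values(kind="stable").index)


def _log_quantities(
    ds: CqDataset, efficiencies: Mapping[str, float] | None
) -> np.ndarray:
    """log2 relative quantity per (sample, gene).

    Reference point is each gene's mean Cq; any per-gene constant cancels
    in ratios and in V, so the choice is cosmetic.  With no efficiencies,
    E = 2 for all genes.
    """
    ref = ds.cq.mean(axis=0)
    if efficiencies is None:
        return ref - ds.cq
    log2e = np.array([np.log2(efficiencies[g]) for g in ds.genes])
    return (ref - ds.cq) * log2e


def genorm_m(
    ds: CqDataset,
    subset: Sequence[str] | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-gene M value on ``subset`` (default: all genes)."""
    if subset is not None:
        ds = ds.subset_genes(list(subset))
    if ds.n_genes < 2:
        raise ValueError("geNorm M needs >= 2 genes")
    if ds.n_samples < 3:
        raise ValueError("geNorm M needs >= 3 samples")
    if np.isnan(ds.cq).any():
        raise ValueError("missing Cq values; impute or drop upstream")
    logq = _log_quantities(ds, efficiencies)
    k = ds.n_genes
    m = np.zeros(k)
    for g in range(k):
        sds = [
            np.std(logq[:, g] - logq[:, h], ddof=1)
            for h in range(k) if h != g
        ]
        m[g] = float(np.mean(sds))
    return pd.Series(m, index=pd.Index(ds.genes, name="gene"), name="M")


def genorm_stepwise(
    ds: CqDataset,
    efficiencies: Mapping[str, float] | None = None,
    v_cutoff: float = V_CUTOFF_DEFAULT,
) -> GeNormResult:
    """Iterative worst-M exclusion down to the most stable pair, plus V.

    Ties at the worst M break toward the gene with the larger Cq SD, then
    lexicographically; tie events are recorded.  The returned ranking gives
    the final pair rank 1.5 each and the excluded genes ranks 3, 4, ...
    counting back from the last exclusion.
    """
    if ds.n_genes < 3:
        raise ValueError("stepwise exclusion needs >= 3 genes")
    initial_m = genorm_m(ds, efficiencies=efficiencies)
    warnings_ = [g for g, m in initial_m.items() if m > M_WARNING_THRESHOLD]

    cq_sd = pd.Series(np.std(ds.cq, axis=0, ddof=1), index=ds.genes)
    remaining = list(ds.genes)
    exclusion: list[str] = []
    trajectory: list[float] = [float(initial_m.mean())]
    ties: list[str] = []
    m = initial_m
    while len(remaining) > 2:
        worst_m = m.max()
        cands = [g for g in remaining if np.isclose(m[g], worst_m, rtol=0, atol=1e-12)]
        if len(cands) > 1:
            ties.append(f"M tie at {worst_m:.6g}: {cands}")
            worst_sd = max(cq_sd[g] for g in cands)
            cands = [g for g in cands if np.isclose(cq_sd[g], worst_sd, rtol=0, atol=1e-12)]
            worst = sorted(cands)[-1]
        else:
            worst = cands[0]
        exclusion.append(worst)
        remaining = [g for g in remaining if g != worst]
        m = genorm_m(ds, subset=remaining, efficiencies=efficiencies)
        trajectory.append(float(m.mean()))

    # order the final pair deterministically: smaller Cq SD first, then name
    pair = tuple(sorted(remaining, key=lambda g: (cq_sd[g], g)))

    rank = pd.Series(index=pd.Index(ds.genes, name="gene"), dtype=float, name="rank")
    rank[pair[0]] = rank[pair[1]] = 1.5
    for pos, g in enumerate(reversed(exclusion), start=3):
        rank[g] = float(pos)

    best_first = [*pair, *reversed(exclusion)]
    v_series, optimal_n = genorm_pairwise_variation(
        ds, best_first, efficiencies=efficiencies, v_cutoff=v_cutoff
    )
    return GeNormResult(
        initial_m=initial_m,
        exclusion_order=exclusion,
        final_pair=pair,  # type: ignore[arg-type]
        m_trajectory=trajectory,
        rank=rank,
        v_series=v_series,
        optimal_n=optimal_n,
        m_warnings=warnings_,
        tie_events=ties,
    )


def genorm_pairwise_variation(
    ds: CqDataset,
    best_first: Sequence[str],
    efficiencies: Mapping[str, float] | None = None,
    v_cutoff: float = V_CUTOFF_DEFAULT,
) -> tuple[pd.Series, int]:
    """V(n/n+1) series over the best-first gene ordering and the optimal n.

    NF_n[s] is the geometric mean of the n best genes' relative quantities
    in sample s; V(n/n+1) = SD_s(log2(NF_n/NF_{n+1})).  The optimal count is
    the smallest n with V below the cutoff, or the full panel size when no
    V passes.
    """
    if ds.n_genes < 3:
        raise ValueError("pairwise variation needs >= 3 genes")
    if list(sorted(best_first)) != sorted(ds.genes):
        raise ValueError("best_first must be a permutation of the dataset's genes")
    ordered = ds.subset_genes(list(best_first))
    logq = _log_quantities(ordered, efficiencies)
    k = ordered.n_genes
    values = {}
    for n in range(2, k):
        nf_n = logq[:, :n].mean(axis=1)        # log2 of geometric mean
        nf_n1 = logq[:, : n + 1].mean(axis=1)
        values[n] = float(np.std(nf_n - nf_n1, ddof=1))
    v_series = pd.Series(values, name="V")
    v_series.index.name = "n"
    passing = [n for n, v in values.items() if v < v_cutoff]
    optimal_n = min(passing) if passing else k
    return v_series, optimal_n
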