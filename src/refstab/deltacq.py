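"""Comparative delta-Cq stability.

Every pair of candidate genes is compared through the per-sample Cq
difference dCq_s = Cq[s,g] - Cq[s,h]; the sample standard deviation of
that difference measures how consistently the pair co-varies.  A gene's
stability is the average of its pairwise SDs against all other candidates:
a low average SD means the gene tracks the rest of the panel and is a good
normalizer.  Shared per-sample loading shifts cancel in the difference,
which is the method's core robustness property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CqDataset


@dataclass
class DeltaCqResult:
    pair_sd: pd.DataFrame  # gene x gene, symmetric, zero diagonal (cycles)
    mean_sd: pd.Series     # per gene, average off-diagonal row (cycles)
    rank: pd.Series        # ascending by mean_sd, average ties

    def ranking(self) -> list[str]:
        return list(self.mean_sd.sort_values(kind="stable").index)


def delta_cq_stability(ds: CqDataset) -> DeltaCqResult:
    """SD of pairwise Cq differences, averaged per gene, with ranks.

    Needs at least 3 samples; with exactly 2 genes both receive the same
    mean SD and the tied rank 1.5 (forced by symmetry).
    """
    if ds.n_samples < 3:
        raise ValueError("delta-Cq stability needs >= 3 samples")
    if ds.n_genes < 2:
        raise ValueError("delta-Cq stability needs >= 2 genes")
    if np.isnan(ds.cq).any():
        raise ValueError("missing Cq values; impute or drop upstream")

    k = ds.n_genes
    pair = np.zeros((k, k))
    for g in range(k):
        for h in range(g + 1, k):
            sd = float(np.std(ds.cq[:, g] - ds.cq[:, h], ddof=1))
            pair[g, h] = pair[h, g] = sd
    mean_sd = pair.sum(axis=1) / (k - 1)
    ranks = stats.rankdata(mean_sd, method="average")

    genes = pd.Index(ds.genes, name="gene")
    return DeltaCqResult(
        pair_sd=pd.DataFrame(pair, index=genes, columns=genes),
        mean_sd=pd.Series(mean_sd, index=genes, name="mean_sd"),
        rank=pd.Series(ranks, index=genes, name="rank"),
    )
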