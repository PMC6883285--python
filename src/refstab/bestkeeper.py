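"""BestKeeper stability statistics.

A candidate reference gene is judged by two descriptors: the standard
deviation of its mean Cq values across all samples (low SD = stable), and
the Pearson correlation of its Cq vector with the BestKeeper index (BKI),
the per-sample geometric mean of all candidates' Cq values (r close to 1 =
comparable expression behavior).  Candidates with SD > 1 cycle are deemed
inappropriate for normalization; remaining genes are ranked separately by
SD (ascending) and by r (descending) and the two ranks are averaged into
the module's mean ranking score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CqDataset

SD_EXCLUSION_CUTOFF = 1.0


@dataclass
class BestKeeperResult:
    """Per-gene BestKeeper descriptors, ranks and exclusion flags."""

    table: pd.DataFrame  # index: gene; columns: sd, r, p, sd_rank, r_rank, mean_rank_score, excluded
    bki: pd.Series       # index: sample; BestKeeper index (cycles)

    @property
    def mean_rank_score(self) -> pd.Series:
        return self.table["mean_rank_score"]

    def ranking(self) -> list[str]:
        """Included genes ordered most-stable first (by mean ranking score)."""
        inc = self.table[~self.table["excluded"]]
        return list(inc.sort_values(["mean_rank_score", "sd"]).index)


def bestkeeper_index(ds: CqDataset) -> pd.Series:
    """Per-sample geometric mean of Cq over all evaluated genes."""
    if np.isnan(ds.cq).any():
        raise ValueError("missing Cq values; impute or drop upstream")
    bki = np.exp(np.mean(np.log(ds.cq), axis=1))
    return pd.Series(bki, index=ds.samples, name="bki")


def bestkeeper(
    ds: CqDataset,
    sd_cutoff: float = SD_EXCLUSION_CUTOFF,
    rank_by_abs_r: bool = False,
) -> BestKeeperResult:
    """Compute BestKeeper SDs, BKI correlations and the mean ranking score.

    All samples are pooled across groups (n-1 SD).  The BKI is built from
    every evaluated gene, including any exceeding the SD cutoff — the
    cutoff governs ranking eligibility, not BKI membership.  Ties receive
    average ranks; excluded genes carry no ranks.  Correlations with
    non-significant p-values are still ranked by their r value; set
    ``rank_by_abs_r=True`` to rank by |r| instead if negative correlations
    appear.
    """
    if ds.n_samples < 3 or ds.n_genes < 2:
        raise ValueError("BestKeeper needs >= 3 samples and >= 2 genes")
    bki = bestkeeper_index(ds)

    sd = np.std(ds.cq, axis=0, ddof=1)
    r = np.empty(ds.n_genes)
    p = np.empty(ds.n_genes)
    bki_vals = bki.to_numpy()
    for j in range(ds.n_genes):
        col = ds.cq[:, j]
        if np.ptp(col) == 0 or np.ptp(bki_vals) == 0:
            r[j], p[j] = np.nan, np.nan
        else:
            r[j], p[j] = stats.pearsonr(col, bki_vals)

    excluded = sd > sd_cutoff
    sd_rank = np.full(ds.n_genes, np.nan)
    r_rank = np.full(ds.n_genes, np.nan)
    inc = ~excluded
    if inc.any():
        sd_rank[inc] = stats.rankdata(sd[inc], method="average")
        key = -np.abs(r[inc]) if rank_by_abs_r else -r[inc]
        r_rank[inc] = stats.rankdata(key, method="average")
    mean_score = (sd_rank + r_rank) / 2.0

    table = pd.DataFrame(
        {
            "sd": sd,
            "r": r,
            "p": p,
            "sd_rank": sd_rank,
            "r_rank": r_rank,
            "mean_rank_score": mean_score,
            "excluded": excluded,
        },
        index=pd.Index(ds.genes, name="gene"),
    )
    return BestKeeperResult(table=table, bki=bki)
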