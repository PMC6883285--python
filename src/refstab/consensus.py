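"""Consensus ranking across the four stability methods.

Each method contributes one score per gene: BestKeeper its (possibly
fractional) mean of SD-rank and correlation-rank, the comparative delta-Cq
method and NormFinder their ordinal ranks, and geNorm its final ranking
with the last surviving pair tied at 1.5 — geNorm cannot order those two.
The overall score is the arithmetic mean of the four (all methods weighted
equally); a geometric-mean variant is available but dampens extreme
scores, so it is not the default.  Genes excluded upstream (replicate QC)
simply never enter any method and are absent from the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bestkeeper import BestKeeperResult
from .deltacq import DeltaCqResult
from .genorm import GeNormResult
from .normfinder import NormFinderResult

METHODS = ("bestkeeper", "deltacq", "genorm", "normfinder")


@dataclass
class ConsensusRanking:
    table: pd.DataFrame  # per gene: the four method scores, overall_score, overall_rank
    aggregation: str

    def ranking(self) -> list[str]:
        return list(self.table.sort_values(["overall_score"], kind="stable").index)

    @property
    def overall_score(self) -> pd.Series:
        return self.table["overall_score"]

    @property
    def overall_rank(self) -> pd.Series:
        return self.table["overall_rank"]


def overall_ranking(
    bestkeeper: BestKeeperResult,
    deltacq: DeltaCqResult,
    genorm: GeNormResult,
    normfinder: NormFinderResult,
    aggregation: str = "arithmetic",
) -> ConsensusRanking:
    """Combine the four method scores into one stability ranking.

    All four results must cover exactly the same gene set; a mismatch is an
    error naming the differing genes.  Ties in the overall score receive
    average overall ranks.
    """
    if aggregation not in ("arithmetic", "geometric"):
        raise ValueError("aggregation must be 'arithmetic' or 'geometric'")
    scores = {
        "bestkeeper": bestkeeper.table["mean_rank_score"],
        "deltacq": deltacq.rank,
        "genorm": genorm.rank,
        "normfinder": normfinder.rank,
    }
    gene_sets = {m: set(s.index) for m, s in scores.items()}
    reference = gene_sets["bestkeeper"]
    for m, gs in gene_sets.items():
        if gs != reference:
            extra = sorted(gs ^ reference)
            raise ValueError(f"gene sets differ between methods ({m}): {extra}")
    genes = list(scores["bestkeeper"].index)
    df = pd.DataFrame({m: s.reindex(genes) for m, s in scores.items()})
    if df.isna().any().any():
        bad = sorted(df.index[df.isna().any(axis=1)])
        raise ValueError(f"genes without a score in some method: {bad}")

    if aggregation == "arithmetic":
        overall = df.mean(axis=1)
    else:
        overall = np.exp(np.log(df).mean(axis=1))
    df["overall_score"] = overall
    df["overall_rank"] = stats.rankdata(overall, method="average")
    df.index.name = "gene"
    return ConsensusRanking(table=df.sort_values("overall_score", kind="stable"),
                            aggregation=aggregation)


@dataclass
class SettingAgreement:
    rank_delta: pd.Series  # per gene: rank in B minus rank in A
    spearman_rho: float
    spearman_p: float


def compare_settings(a: ConsensusRanking, b: ConsensusRanking) -> SettingAgreement:
    """Agreement between two consensus rankings (e.g. the two Cq settings).

    Reports each gene's signed overall-rank difference and the Spearman
    correlation of the overall scores.
    """
    genes_a, genes_b = set(a.table.index), set(b.table.index)
    if genes_a != genes_b:
        raise ValueError(f"gene sets differ: {sorted(genes_a ^ genes_b)}")
    genes = list(a.table.index)
    delta = b.table["overall_rank"].reindex(genes) - a.table["overall_rank"].reindex(genes)
    rho, p = stats.spearmanr(
        a.table["overall_score"].reindex(genes), b.table["overall_score"].reindex(genes)
    )
    return SettingAgreement(rank_delta=delta, spearman_rho=float(rho), spearman_p=float(p))
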