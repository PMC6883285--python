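"""Convenience drivers chaining QC, the four stability methods and consensus."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .bestkeeper import BestKeeperResult, bestkeeper
from .consensus import ConsensusRanking, overall_ranking
from .dataset import CqDataset
from .deltacq import DeltaCqResult, delta_cq_stability
from .genorm import GeNormResult, genorm_stepwise
from .normfinder import NormFinderResult, normfinder
from .qc import (
    DUPLICATE_SD_CUTOFF,
    ReplicateQCReport,
    aggregate_technical_replicates,
    apply_exclusions,
    flag_high_variability_candidates,
)


@dataclass
class StabilitySuite:
    dataset: CqDataset
    qc_report: ReplicateQCReport | None
    bestkeeper: BestKeeperResult
    deltacq: DeltaCqResult
    genorm: GeNormResult
    normfinder: NormFinderResult
    consensus: ConsensusRanking


def run_stability_suite(
    ds: CqDataset,
    sd_cutoff: float = DUPLICATE_SD_CUTOFF,
    keep: Iterable[str] = (),
    aggregation: str = "arithmetic",
    apply_qc: bool = True,
) -> StabilitySuite:
    """Aggregate replicates, apply the duplicate-SD screen, run all four
    stability methods on the surviving genes and build the consensus.

    ``keep`` lists genes to retain despite a duplicate-SD flag.  With
    ``apply_qc=False`` the replicate screen is skipped (replicates are
    still averaged if present).
    """
    qc_report = None
    if ds.replicate_cq is not None:
        ds, qc_report = aggregate_technical_replicates(ds)
        if apply_qc:
            decisions = flag_high_variability_candidates(
                qc_report, ds, sd_cutoff=sd_cutoff, keep=keep
            )
            ds = apply_exclusions(ds, decisions)
    bk = bestkeeper(ds)
    # genes past the SD > 1 appropriateness cutoff carry no BestKeeper rank;
    # a consensus needs four scores per gene, so drop them from the panel
    # and re-evaluate the survivors
    flagged = list(bk.table.index[bk.table["excluded"]])
    if flagged:
        ds = ds.subset_genes([g for g in ds.genes if g not in flagged])
        bk = bestkeeper(ds)
    dc = delta_cq_stability(ds)
    gn = genorm_stepwise(ds)
    nf = normfinder(ds)
    cons = overall_ranking(bk, dc, gn, nf, aggregation=aggregation)
    return StabilitySuite(
        dataset=ds, qc_report=qc_report, bestkeeper=bk, deltacq=dc,
        genorm=gn, normfinder=nf, consensus=cons,
    )
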