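"""NormFinder model-based stability estimation.

Cq values are treated as log-scale expression measures and modeled, within
each experimental group, as gene effect + sample effect + group-specific
gene deviation + noise.  For every gene the model yields

* a bias-corrected **intra-group variance** estimate per group, from the
  double-centered residuals of the group's samples x genes submatrix;
* an **inter-group deviation** d per group — how far the gene's group mean
  departs from its overall mean after removing group-level shifts —
  shrunk toward zero by an empirical-Bayes factor that accounts for the
  sampling noise of d;
* the **stability value** rho: the average over groups of
  |shrunken d| + posterior SD of d.  Low rho = stable.

A candidate combining small systematic group differences with low
within-group scatter gets a small rho.  Because two genes with opposite
group deviations cancel when averaged, the best *pair* of genes (smallest
combined stability over all unordered pairs) can beat any single gene.

Sign conventions do not matter: all quantities are variances or absolute
deviations, so running on Cq directly (which is -log2 quantity under
perfect doubling) is equivalent to running on log expression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CqDataset


@dataclass
class NormFinderResult:
    rho: pd.Series                 # per-gene stability value
    rank: pd.Series                # ascending in rho, average ties
    intra_var: pd.DataFrame        # gene x group intra-group variance (log-scale^2)
    inter_var: pd.DataFrame        # gene x group shrunken deviation d (log-scale)
    gamma_sq: float                # estimated variance of group deviations
    best_pair: tuple[str, str] | None = None
    best_pair_rho: float | None = None
    grouped: bool = True
    notes: list[str] = field(default_factory=list)

    def ranking(self) -> list[str]:
        return list(self.rho.sort_values(kind="stable").index)


def _group_decomposition(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene bias-corrected residual variance and gene means for one group.

    ``y`` is (n_samples_in_group, n_genes).  Residuals are double-centered
    (gene and sample means removed).  The naive per-gene residual variance
    v_i = sum_j z_ij^2 / (n-1) is biased because centering mixes the other
    genes' noise in; with k genes the unbiased reconstruction is

        sigma2_i = k/(k-2) * v_i - sum(v) / ((k-1)(k-2))

    derived by moment-matching E[v_i] = sigma2_i (k-2)/k + S/k^2 with
    S = sum_i sigma2_i.  Estimates are floored at zero.
    """
    n, k = y.shape
    if k < 3:
        raise ValueError("NormFinder needs >= 3 genes for the variance decomposition")
    gene_means = y.mean(axis=0)
    z = y - gene_means[None, :] - y.mean(axis=1)[:, None] + y.mean()
    v = (z ** 2).sum(axis=0) / (n - 1)
    sigma2 = k / (k - 2) * v - v.sum() / ((k - 1) * (k - 2))
    return np.maximum(sigma2, 0.0), gene_means


def normfinder(ds: CqDataset, fallback_single_group: bool = True) -> NormFinderResult:
    """Per-gene stability values with intra-/inter-group decomposition.

    Grouped mode requires >= 2 groups with >= 2 samples each.  With a
    single group (and ``fallback_single_group``) the stability value
    degrades to the square root of the bias-corrected per-gene variance,
    flagged in ``notes``.
    """
    if np.isnan(ds.cq).any():
        raise ValueError("missing Cq values; impute or drop upstream")
    labels = ds.group_labels
    genes = pd.Index(ds.genes, name="gene")
    gvec = ds.group_vector()

    if len(labels) == 1:
        if not fallback_single_group:
            raise ValueError("grouped mode requires >= 2 groups")
        sigma2, _ = _group_decomposition(ds.cq)
        rho = pd.Series(np.sqrt(sigma2), index=genes, name="rho")
        rank = pd.Series(
            _avg_rank(rho.to_numpy()), index=genes, name="rank"
        )
        intra = pd.DataFrame({labels[0]: sigma2}, index=genes)
        inter = pd.DataFrame({labels[0]: np.zeros(len(genes))}, index=genes)
        return NormFinderResult(
            rho=rho, rank=rank, intra_var=intra, inter_var=inter,
            gamma_sq=0.0, grouped=False,
            notes=["single-group fallback: rho = per-gene residual SD"],
        )

    n_g: dict[str, int] = {}
    sigma2 = np.zeros((ds.n_genes, len(labels)))   # gene x group
    a = np.zeros((ds.n_genes, len(labels)))        # group-centered gene means
    for j, lab in enumerate(labels):
        rows = gvec == lab
        n = int(rows.sum())
        if n < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        n_g[lab] = n
        y = ds.cq[rows, :]
        s2, gene_means = _group_decomposition(y)
        sigma2[:, j] = s2
        a[:, j] = gene_means - gene_means.mean()   # remove group-level shift

    N = sum(n_g.values())
    weights = np.array([n_g[lab] for lab in labels], dtype=float)
    # raw inter-group deviation: group-centered gene mean minus its
    # size-weighted average over groups (so sum_g n_g d_ig = 0 per gene)
    d = a - (a @ weights)[:, None] / N

    G, k = len(labels), ds.n_genes
    u = sigma2 / weights[None, :]                  # sampling variance of a group mean
    gamma_sq = max(0.0, float((d ** 2).sum() / ((G - 1) * (k - 1)) - u.mean()))

    notes: list[str] = []
    if gamma_sq == 0.0:
        # no evidence of group-specific deviations: stability is driven by
        # the intra-group uncertainty alone
        notes.append("gamma^2 floored at 0: no detectable inter-group variation")
        d_shrunk = np.zeros_like(d)
        stab = np.sqrt(u)
    else:
        shrink = gamma_sq / (gamma_sq + u)
        d_shrunk = d * shrink
        post_var = gamma_sq * u / (gamma_sq + u)
        stab = np.abs(d_shrunk) + np.sqrt(post_var)
    rho_vals = stab.mean(axis=1)

    rho = pd.Series(rho_vals, index=genes, name="rho")
    rank = pd.Series(_avg_rank(rho_vals), index=genes, name="rank")
    result = NormFinderResult(
        rho=rho,
        rank=rank,
        intra_var=pd.DataFrame(sigma2, index=genes, columns=labels),
        inter_var=pd.DataFrame(d_shrunk, index=genes, columns=labels),
        gamma_sq=gamma_sq,
        notes=notes,
    )
    if ds.n_genes >= 2:
        pair, pair_rho = _best_pair(d_shrunk, u, gamma_sq, ds.genes)
        result.best_pair = pair
        result.best_pair_rho = pair_rho
    return result


def _avg_rank(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(values, method="average")


def _best_pair(
    d_shrunk: np.ndarray, u: np.ndarray, gamma_sq: float, genes: list[str]
) -> tuple[tuple[str, str], float]:
    """Exhaustive search for the two-gene combination with minimal stability.

    For a pair the group deviation is the average of the members' shrunken
    deviations and the posterior variance propagates as the mean of the
    members' posterior variances divided by 2 (average of two independent
    estimates).
    """
    if gamma_sq > 0:
        post_var = gamma_sq * u / (gamma_sq + u)
    else:
        post_var = u
    best: tuple[tuple[str, str], float] | None = None
    for i, j in itertools.combinations(range(len(genes)), 2):
        d_pair = 0.5 * (d_shrunk[i] + d_shrunk[j])
        v_pair = 0.25 * (post_var[i] + post_var[j])
        rho = float(np.mean(np.abs(d_pair) + np.sqrt(v_pair)))
        if best is None or rho < best[1] - 1e-15 or (
            abs(rho - best[1]) <= 1e-15 and (genes[i], genes[j]) < best[0]
        ):
            best = ((genes[i], genes[j]), rho)
    assert best is not None
    return best


def normfinder_best_pair(
    result: NormFinderResult, ds: CqDataset
) -> tuple[tuple[str, str], float]:
    """Best two-gene combination from a grouped NormFinder fit."""
    if not result.grouped:
        raise ValueError("best-pair search requires grouped mode")
    if result.best_pair is None or result.best_pair_rho is None:
        raise ValueError("result carries no pair search (fewer than 2 genes)")
    return result.best_pair, result.best_pair_rho
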