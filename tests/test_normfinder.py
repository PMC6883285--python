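from __future__ import annotations

import numpy as np
import pytest

from refstab.dataset import CqDataset
from refstab.normfinder import normfinder, normfinder_best_pair

from conftest import random_dataset
from oracles import normfinder_bruteforce


def _grouped_dataset(rng, n_per_group=(4, 4, 4), n_genes=5, sigmas=None, shifts=None):
    sigmas = sigmas if sigmas is not None else [0.3] * n_genes
    labels = [f"grp{t}" for t in range(len(n_per_group))]
    samples, groups = [], {}
    for lab, n in zip(labels, n_per_group):
        for i in range(n):
            s = f"{lab}_{i}"
            samples.append(s)
            groups[s] = lab
    base = rng.uniform(20, 30, size=n_genes)
    cq = np.empty((len(samples), n_genes))
    for i, s in enumerate(samples):
        for j in range(n_genes):
            shift = shifts.get((groups[s], j), 0.0) if shifts else 0.0
            cq[i, j] = base[j] + shift + rng.normal(0, sigmas[j])
    return CqDataset(samples, [f"g{j}" for j in range(n_genes)], cq, groups)


def test_constant_gene_attains_minimal_rho(rng):
    ds = _grouped_dataset(rng, n_per_group=(12, 12, 12), n_genes=5,
                          sigmas=[0.0, 0.4, 0.4, 0.4, 0.4])
    res = normfinder(ds)
    assert res.rho.idxmin() == "g0"
    # the other genes' noise leaks marginally through the panel centering,
    # so the variance estimate is near zero rather than identically zero
    assert np.all(res.intra_var.loc["g0"] < 0.02)
    assert np.all(np.abs(res.inter_var.loc["g0"]) < 0.1)


def test_matches_bruteforce_loops(rng):
    ds = _grouped_dataset(rng, n_per_group=(4, 5, 6), n_genes=6)
    res = normfinder(ds)
    oracle = normfinder_bruteforce(ds.cq.tolist(), list(ds.group_vector()))
    np.testing.assert_allclose(res.rho, oracle["rho"], rtol=1e-10)
    assert res.gamma_sq == pytest.approx(oracle["gamma_sq"], rel=1e-10)
    for lab in ds.group_labels:
        np.testing.assert_allclose(res.intra_var[lab], oracle["sigma2"][lab], rtol=1e-10)
        np.testing.assert_allclose(res.inter_var[lab], oracle["d_shrunk"][lab], rtol=1e-10)


def test_planted_group_shift_ranks_worst(rng):
    shifts = {("grp2", 2): 1.0}  # one gene moves 1 cycle in one group
    ds = _grouped_dataset(rng, n_per_group=(4, 4, 4), n_genes=5, shifts=shifts)
    res = normfinder(ds)
    assert res.rho.idxmax() == "g2"


def test_weighted_group_deviations_sum_to_zero(rng):
    ds = _grouped_dataset(rng, n_per_group=(3, 5, 4), n_genes=5)
    res = normfinder(ds)
    weights = np.array([sum(1 for s in ds.samples if ds.groups[s] == lab)
                        for lab in ds.group_labels], dtype=float)
    if res.gamma_sq > 0:
        raw = res.inter_var.to_numpy() * (
            res.gamma_sq + res.intra_var.to_numpy() / weights[None, :]
        ) / res.gamma_sq  # undo shrinkage
        np.testing.assert_allclose(raw @ weights, 0.0, atol=1e-9)


def test_rho_invariant_to_sample_and_gene_shifts(rng):
    ds = _grouped_dataset(rng, n_genes=5)
    rho0 = normfinder(ds).rho
    shifted = ds.subset_samples(ds.samples)
    shifted.cq += rng.normal(0, 1.5, size=(shifted.n_samples, 1))  # loading
    shifted.cq += rng.normal(0, 2.0, size=(1, shifted.n_genes))    # abundance
    rho1 = normfinder(shifted).rho
    np.testing.assert_allclose(rho0.to_numpy(), rho1.to_numpy(), atol=1e-10)


def test_null_shrunken_deviation_decreases_with_group_size():
    means = []
    for n in (3, 6, 12, 24):
        vals = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            ds = _grouped_dataset(rng, n_per_group=(n, n, n), n_genes=6)
            res = normfinder(ds)
            vals.append(np.mean(np.abs(res.inter_var.to_numpy())))
        means.append(np.mean(vals))
    assert all(a > b for a, b in zip(means, means[1:]))


def test_intra_group_sd_recovery():
    """Planted intra-group SDs are recovered within 20% RMSE at n = 20."""
    sigmas = np.array([0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6])
    estimates = []
    for seed in range(500):
        rng = np.random.default_rng(2000 + seed)
        ds = _grouped_dataset(
            rng, n_per_group=(20, 20, 20), n_genes=8, sigmas=sigmas
        )
        res = normfinder(ds)
        estimates.append(np.sqrt(res.intra_var.to_numpy().mean(axis=1)))
    est = np.array(estimates)
    rmse = np.sqrt(np.mean((est - sigmas[None, :]) ** 2, axis=0))
    assert np.all(rmse / sigmas < 0.20)


def test_single_group_fallback_orders_by_residual_sd(rng):
    ds = _grouped_dataset(rng, n_per_group=(12,), n_genes=5,
                          sigmas=[0.1, 0.5, 0.2, 0.4, 0.3])
    res = normfinder(ds)
    assert not res.grouped and res.notes
    # fallback rho is the bias-corrected residual SD: ordering must match
    # the ordering of the per-group residual variance decomposition
    order_by_rho = list(res.rho.sort_values().index)
    order_by_var = list(res.intra_var.iloc[:, 0].sort_values().index)
    assert order_by_rho == order_by_var


def test_mirrored_pair_beats_singles(rng):
    """Two genes whose group deviations are exact mirror images cancel when
    combined, so the pair beats either member alone."""
    # with three genes and gene 1 the exact mirror of gene 0, the panel
    # centering leaves gene 2 with near-zero deviation, so the only pair
    # whose group differences cancel is (g0, g1)
    shifts = {("grp0", 0): 0.8, ("grp1", 0): -0.8}
    ds = _grouped_dataset(rng, n_per_group=(6, 6), n_genes=3,
                          sigmas=[0.15] * 3, shifts=shifts)
    ds.cq[:, 1] = 50.0 - ds.cq[:, 0]  # exact mirror of gene 0
    res = normfinder(ds)
    pair, pair_rho = normfinder_best_pair(res, ds)
    assert set(pair) == {"g0", "g1"}
    assert pair_rho < min(res.rho["g0"], res.rho["g1"])


def test_best_pair_matches_exhaustive_enumeration(rng):
    ds = _grouped_dataset(rng, n_per_group=(5, 5, 5), n_genes=5)
    res = normfinder(ds)
    oracle = normfinder_bruteforce(ds.cq.tolist(), list(ds.group_vector()))
    (i, j), rho = oracle["best_pair"]
    assert set(res.best_pair) == {ds.genes[i], ds.genes[j]}
    assert res.best_pair_rho == pytest.approx(rho, rel=1e-10)


def test_group_with_single_sample_rejected(rng):
    ds = _grouped_dataset(rng, n_per_group=(4, 1), n_genes=4)
    with pytest.raises(ValueError, match="fewer than 2"):
        normfinder(ds)
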