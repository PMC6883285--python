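from __future__ import annotations

import numpy as np
import pytest

from refstab.deltacq import delta_cq_stability
from refstab.efficiency import correct_baseline, estimate_efficiencies, reaction_efficiency_and_cq
from refstab.genorm import genorm_m
from refstab.normfinder import normfinder
from refstab.pipeline import run_stability_suite
from refstab.qc import aggregate_technical_replicates
from refstab.simulate import (
    CurveConfig,
    GeneSpec,
    SimulationConfig,
    paper_like_config,
    simulate_amplification_curves,
    simulate_cq_dataset,
)


def test_same_seed_bit_identical():
    cfg = paper_like_config(seed=5, with_curves=True)
    ds1, t1 = simulate_cq_dataset(cfg)
    ds2, t2 = simulate_cq_dataset(paper_like_config(seed=5, with_curves=True))
    np.testing.assert_array_equal(ds1.replicate_cq, ds2.replicate_cq)
    assert t1.loading == t2.loading
    c1, _ = simulate_amplification_curves(cfg)
    c2, _ = simulate_amplification_curves(paper_like_config(seed=5, with_curves=True))
    for a, b in zip(c1, c2):
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)


def test_paper_like_shape_and_ranges():
    ds, truth = simulate_cq_dataset(paper_like_config(seed=1))
    assert ds.cq.shape == (16, 11)
    assert ds.replicate_cq.shape == (16, 11, 2)
    counts = {g: sum(1 for s in ds.samples if ds.groups[s] == g) for g in ds.group_labels}
    assert counts == {"non-treated": 5, "sham": 6, "SNI": 5}
    means = ds.cq.mean(axis=0)
    assert means.min() > 17 and means.max() < 33


def test_noise_free_config_gives_degenerate_stability():
    genes = [GeneSpec(f"g{j}", 20.0 + 2 * j, 0.0) for j in range(4)]
    cfg = SimulationConfig(
        n_per_group={"a": 3, "b": 3}, genes=genes,
        loading_sd=0.4, replicate_sd=0.0, seed=9,
    )
    ds, _ = simulate_cq_dataset(cfg)
    agg, _ = aggregate_technical_replicates(ds)
    np.testing.assert_allclose(genorm_m(agg).to_numpy(), 0.0, atol=1e-12)
    np.testing.assert_allclose(
        delta_cq_stability(agg).mean_sd.to_numpy(), 0.0, atol=1e-12
    )


def test_loading_term_cancels_in_pairwise_methods():
    """Regenerating with a 10x larger loading SD consumes the same random
    stream, so the pairwise statistics must be bit-comparable."""
    genes = [GeneSpec(f"g{j}", 22.0 + j, 0.1 + 0.1 * j) for j in range(4)]
    base = SimulationConfig(n_per_group={"a": 4, "b": 4}, genes=genes,
                            loading_sd=0.0, seed=3)
    big = SimulationConfig(n_per_group={"a": 4, "b": 4}, genes=genes,
                           loading_sd=3.0, seed=3)
    ds0, _ = simulate_cq_dataset(base)
    ds1, _ = simulate_cq_dataset(big)
    a0, _ = aggregate_technical_replicates(ds0)
    a1, _ = aggregate_technical_replicates(ds1)
    np.testing.assert_allclose(
        delta_cq_stability(a0).pair_sd.values,
        delta_cq_stability(a1).pair_sd.values,
        rtol=0, atol=1e-10,
    )
    np.testing.assert_allclose(
        normfinder(a0).rho.to_numpy(), normfinder(a1).rho.to_numpy(),
        rtol=0, atol=1e-10,
    )


def test_planted_shift_gene_flagged_by_suite():
    ds, truth = simulate_cq_dataset(paper_like_config(seed=11))
    suite = run_stability_suite(ds, apply_qc=False)
    assert suite.normfinder.ranking()[-1] == "sno292"
    assert "sno292" in suite.consensus.ranking()[-2:]
    # ground truth agrees: the shifted gene carries the largest perturbation
    assert truth.stability_order[-1] == "sno292"


def test_ground_truth_order_is_ascending_perturbation():
    _, truth = simulate_cq_dataset(paper_like_config(seed=0))
    values = [truth.total_perturbation[g] for g in truth.stability_order]
    assert values == sorted(values)


def test_curve_truth_closed_form_and_recovery():
    genes = [GeneSpec("g", 25.0, 0.1)]
    cfg = SimulationConfig(
        n_per_group={"a": 2}, genes=genes, seed=0,
        curve=CurveConfig(efficiencies={"g": 2.0}, f0=0.001, baseline=0.0,
                          plateau=None, noise_sd=0.0),
    )
    curves, truth = simulate_amplification_curves(cfg)
    well = curves[0].well_id
    assert truth.true_threshold_cq[well] == pytest.approx(np.log2(100))
    corr = correct_baseline(curves[0], baseline_cycles=None)
    est = reaction_efficiency_and_cq(corr, threshold=0.1)
    assert est.cq_threshold == pytest.approx(np.log2(100), abs=0.01)
    assert est.efficiency == pytest.approx(2.0, abs=1e-12)


def test_noiseless_efficiency_recovered_exactly():
    genes = [GeneSpec("g", 25.0, 0.1)]
    cfg = SimulationConfig(
        n_per_group={"a": 1}, genes=genes, seed=0,
        curve=CurveConfig(efficiencies={"g": 1.8}, f0=1e-6, baseline=0.0,
                          plateau=None, noise_sd=0.0),
    )
    curves, _ = simulate_amplification_curves(cfg)
    ests = estimate_efficiencies(curves, baseline_cycles=None, min_r_squared=None)
    assert ests[0].efficiency == pytest.approx(1.8, abs=1e-12)


def test_efficiency_rmse_grows_with_fluorescence_noise():
    rmses = []
    for sd in (0.0, 0.002, 0.01, 0.05):
        errs = []
        for seed in range(8):
            genes = [GeneSpec("g", 25.0, 0.1)]
            cfg = SimulationConfig(
                n_per_group={"a": 4}, genes=genes, seed=100 + seed,
                curve=CurveConfig(efficiencies={"g": 1.9}, f0=1e-7,
                                  baseline=0.0, plateau=None, noise_sd=sd),
            )
            curves, truth = simulate_amplification_curves(cfg)
            ests = estimate_efficiencies(curves, baseline_cycles=None,
                                         min_r_squared=None)
            errs += [
                (e.efficiency - truth.true_efficiency[e.well_id]) ** 2
                for e in ests if np.isfinite(e.efficiency)
            ]
        rmses.append(float(np.sqrt(np.mean(errs))))
    assert all(a < b for a, b in zip(rmses, rmses[1:]))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="unknown group"):
        SimulationConfig(
            n_per_group={"a": 3},
            genes=[GeneSpec("g", 25.0, 0.1, group_effects={"zz": 1.0})],
        )
    with pytest.raises(ValueError, match="negative"):
        SimulationConfig(n_per_group={"a": 3}, genes=[GeneSpec("g", 25.0, -0.1)])
    cfg = SimulationConfig(
        n_per_group={"a": 2}, genes=[GeneSpec("g", 25.0, 0.1)], seed=0,
        curve=CurveConfig(efficiencies={"g": 2.3}),
    )
    with pytest.raises(ValueError, match="outside"):
        simulate_amplification_curves(cfg)
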