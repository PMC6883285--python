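from __future__ import annotations

import numpy as np
import pytest

from refstab.dataset import AmplificationCurve
from refstab.efficiency import (
    FLAG_EFFICIENCY_OUTLIER,
    FLAG_FAILED,
    FLAG_NO_PLATEAU,
    amplicon_efficiency_summary,
    compare_efficiency_by_factor,
    correct_baseline,
    estimate_efficiencies,
    flag_efficiency_outliers,
    reaction_efficiency_and_cq,
    window_of_linearity,
    window_of_linearity_array,
)

from oracles import anova_bruteforce


def exp_curve(e=2.0, f0=0.001, n=40, baseline=0.0):
    c = np.arange(1, n + 1, dtype=float)
    return AmplificationCurve("w1", "gX", "s1", baseline + f0 * np.power(e, c))


def test_baseline_subtraction_recovers_exponential_tail():
    curve = exp_curve(e=2.0, f0=1e-9, baseline=0.05)
    corr = correct_baseline(curve, baseline_cycles=(3, 15))
    truth = 1e-9 * np.power(2.0, np.arange(1, 41, dtype=float))
    # late cycles: the early-cycle exponential contribution bounds the error
    tail = slice(25, 40)
    contrib = np.mean(truth[2:15])
    np.testing.assert_allclose(corr.corrected[tail], truth[tail], atol=2 * contrib)
    assert corr.amplified


def test_zero_baseline_passthrough():
    curve = exp_curve()
    corr = correct_baseline(curve, baseline_cycles=None)
    np.testing.assert_array_equal(corr.corrected, curve.fluorescence)


def test_flat_curve_flagged_non_amplifying():
    flat = AmplificationCurve("w", "g", "s", np.full(40, 0.05))
    corr = correct_baseline(flat)
    assert not corr.amplified
    ests = estimate_efficiencies([flat])
    assert ests[0].flags == {"non_amplifying"}


def test_window_earliest_on_noiseless_exponential():
    corr = correct_baseline(exp_curve(), baseline_cycles=None)
    # every window has R^2 = 1; tie-break picks the earliest below plateau
    assert window_of_linearity(corr, points=4) == (1, 4)


def test_window_respects_hard_plateau():
    c = np.arange(1, 41, dtype=float)
    f = np.where(c <= 25, 0.001 * 2.0 ** np.minimum(c, 25), 0.001 * 2.0 ** 25)
    win = window_of_linearity_array(f, points=4)
    assert 1 <= win[0] and win[1] <= 25
    # oracle: brute-force scan of all monotone windows confirms optimality
    best = None
    for start in range(0, 37):
        seg = f[start : start + 4]
        if np.any(np.diff(seg) <= 0) or np.any(seg > 0.9 * f.max()):
            continue
        x = np.arange(start + 1, start + 5, dtype=float)
        r2 = np.corrcoef(x, np.log10(seg))[0, 1] ** 2
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, (start + 1, start + 4))
    assert win == best[1]


def test_window_avoids_spiked_cycle():
    c = np.arange(1, 41, dtype=float)
    f = 0.001 * 2.0 ** c
    f[19] *= 3.0  # spike at cycle 20
    win = window_of_linearity_array(f, points=4)
    assert not (win[0] <= 20 <= win[1])


@pytest.mark.parametrize("e", [1.7, 1.8, 1.9, 2.0])
def test_exact_efficiency_recovery(e):
    corr = correct_baseline(exp_curve(e=e), baseline_cycles=None)
    est = reaction_efficiency_and_cq(corr, threshold=0.1)
    assert est.efficiency == pytest.approx(e, abs=1e-12)
    expected_cq = np.log(100.0) / np.log(e)  # f0 * e^cq = 0.1 with f0 = 0.001
    assert est.cq_regression == pytest.approx(expected_cq, abs=1e-9)
    assert est.cq_threshold == pytest.approx(expected_cq, abs=1e-9)


def test_doubling_closed_form_cq():
    corr = correct_baseline(exp_curve(e=2.0, f0=0.001), baseline_cycles=None)
    est = reaction_efficiency_and_cq(corr, threshold=0.1)
    assert est.efficiency == pytest.approx(2.0, abs=1e-12)
    assert est.cq_regression == pytest.approx(np.log2(100), abs=1e-9)  # ~6.6439


def test_regression_and_threshold_cq_agree_on_clean_curves():
    for e in (1.72, 1.85, 1.95):
        corr = correct_baseline(exp_curve(e=e, f0=1e-6), baseline_cycles=None)
        est = reaction_efficiency_and_cq(corr, threshold=0.1)
        assert abs(est.cq_regression - est.cq_threshold) < 0.05


def test_refined_baseline_near_exact_on_constant_offset():
    curve = exp_curve(e=1.8, f0=1e-8, baseline=0.05)
    corr = correct_baseline(curve, baseline_cycles=(3, 15), refine=True)
    est = reaction_efficiency_and_cq(corr, threshold=0.1)
    assert est.efficiency == pytest.approx(1.8, abs=1e-6)


def test_noise_shrinking_converges_to_closed_form():
    rng = np.random.default_rng(11)
    e, f0 = 1.9, 1e-6
    truth_cq = np.log(0.1 / f0) / np.log(e)
    errors = []
    for sd in (3e-3, 1e-3, 3e-4, 1e-4, 0.0):
        errs_e, errs_c = [], []
        for _ in range(20):
            f = f0 * np.power(e, np.arange(1, 41.0)) + rng.normal(0, sd, 40)
            curve = AmplificationCurve("w", "g", "s", f)
            corr = correct_baseline(curve, baseline_cycles=None)
            est = reaction_efficiency_and_cq(corr, threshold=0.1)
            errs_e.append(abs(est.efficiency - e))
            errs_c.append(abs(est.cq_threshold - truth_cq))
        errors.append((np.mean(errs_e), np.mean(errs_c)))
    assert errors[-1][0] < 1e-10 and errors[-1][1] < 1e-10
    assert errors[0][0] > errors[-2][0] and errors[0][1] > errors[-2][1]


def test_baseline_misspecification_lowers_efficiency_monotonically():
    f = 0.001 * np.power(2.0, np.arange(1, 41.0))
    window = (12, 15)
    effs = []
    for delta in (0.0, 0.002, 0.004, 0.008, 0.016):
        # +delta = residual background the baseline step failed to remove
        curve = AmplificationCurve("w", "g", "s", f + delta)
        corr = correct_baseline(curve, baseline_cycles=None)
        est = reaction_efficiency_and_cq(corr, window=window)
        effs.append(est.efficiency)
    assert all(a > b for a, b in zip(effs, effs[1:]))
    assert effs[0] == pytest.approx(2.0, abs=1e-12)


def test_declining_curve_flagged_failed():
    f = 0.5 - 0.01 * np.arange(1, 41.0)
    curve = AmplificationCurve("w", "g", "s", f)
    corr = correct_baseline(curve, baseline_cycles=None)
    with pytest.raises(ValueError):
        window_of_linearity(corr)


def test_threshold_never_crossed_gives_missing_cq():
    corr = correct_baseline(exp_curve(e=1.2, f0=1e-6), baseline_cycles=None)
    est = reaction_efficiency_and_cq(corr, threshold=10.0, min_r_squared=None)
    assert est.cq_threshold is None
    assert est.efficiency == pytest.approx(1.2, abs=1e-12)


def _mk_estimates(effs, flags=None):
    from refstab.efficiency import EfficiencyEstimate

    flags = flags or [set() for _ in effs]
    return [
        EfficiencyEstimate(f"w{i}", "gX", f"s{i}", e, 0.999, 20.0, 20.0, (10, 13), fl)
        for i, (e, fl) in enumerate(zip(effs, flags))
    ]


def test_amplicon_summary_policies():
    ests = _mk_estimates([1.9, 1.9, 1.9])
    s = amplicon_efficiency_summary(ests)
    assert s.mean_efficiency == pytest.approx(1.9) and s.n_excluded == 0

    ests = _mk_estimates([1.9, 1.9, 1.5], flags=[set(), set(), {FLAG_NO_PLATEAU}])
    s = amplicon_efficiency_summary(ests)
    assert s.mean_efficiency == pytest.approx(1.9) and s.n_excluded == 1

    ests = _mk_estimates([1.9, 1.9, 1.4], flags=[set(), set(), {FLAG_EFFICIENCY_OUTLIER}])
    incl = amplicon_efficiency_summary(ests, include_outliers=True)
    excl = amplicon_efficiency_summary(ests, include_outliers=False)
    assert incl.mean_efficiency != excl.mean_efficiency
    assert excl.mean_efficiency == pytest.approx(1.9)

    clean = _mk_estimates([1.9, 1.88, 1.92])
    incl = amplicon_efficiency_summary(clean, include_outliers=True)
    excl = amplicon_efficiency_summary(clean, include_outliers=False)
    assert incl == excl  # policies differ only when an outlier flag is present


def test_outlier_flagging_by_mad():
    ests = _mk_estimates([1.88, 1.90, 1.89, 1.91, 1.90, 1.2])
    flag_efficiency_outliers(ests, mad_multiplier=3.0)
    assert FLAG_EFFICIENCY_OUTLIER in ests[-1].flags
    assert all(FLAG_EFFICIENCY_OUTLIER not in e.flags for e in ests[:-1])


def test_factor_comparison_degenerate_and_closed_form():
    ests = _mk_estimates([1.8, 1.8, 1.8, 1.8])
    factor = {"w0": "day1", "w1": "day1", "w2": "day2", "w3": "day2"}
    (rep,) = compare_efficiency_by_factor(ests, factor)
    assert rep.degenerate and rep.f_statistic == 0.0 and rep.p_value == 1.0

    effs = [1.80, 1.82, 1.84, 1.90, 1.92, 1.94]
    ests = _mk_estimates(effs)
    factor = {f"w{i}": ("day1" if i < 3 else "day2") for i in range(6)}
    (rep,) = compare_efficiency_by_factor(ests, factor)
    f_expected, _ = anova_bruteforce([effs[:3], effs[3:]])
    assert rep.f_statistic == pytest.approx(f_expected, rel=1e-10)


def test_factor_comparison_null_rejection_rate():
    """Under a true null the per-amplicon factor test rejects at ~alpha."""
    rng = np.random.default_rng(123)
    rejections = 0
    n_rep = 1000
    factor = {f"w{i}": f"day{i // 5}" for i in range(15)}
    for _ in range(n_rep):
        ests = _mk_estimates(rng.normal(1.85, 0.03, 15))
        (rep,) = compare_efficiency_by_factor(ests, factor)
        rejections += rep.p_value < 0.05
    rate = rejections / n_rep
    ci = 3 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < ci
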