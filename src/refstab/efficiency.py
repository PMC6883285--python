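"""PCR efficiency and Cq estimation from raw amplification curves.

Each well's fluorescence series is baseline-corrected, a short window of
cycles where log-fluorescence is most linear in cycle number (the window
of linearity) is located, and a regression of log10(fluorescence) on cycle
within that window yields the per-reaction amplification efficiency
``E = 10**slope`` (per-cycle fold change, 2 = perfect doubling) and a
fractional quantitation cycle.  Two Cq definitions are reported side by
side: the regression Cq (fitted line crossing a fluorescence threshold)
and the fixed-threshold Cq (log-linear interpolation between the two
cycles bracketing the threshold), which agree on clean exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dataset import AmplificationCurve

FLAG_NO_PLATEAU = "no_plateau"
FLAG_EFFICIENCY_OUTLIER = "efficiency_outlier"
FLAG_BELOW_R2 = "below_r2"
FLAG_NON_AMPLIFYING = "non_amplifying"
FLAG_FAILED = "failed_reaction"


@dataclass
class CorrectedCurve:
    """Baseline-corrected fluorescence with amplification status."""

    curve: AmplificationCurve
    corrected: np.ndarray
    baseline: float
    amplified: bool

    @property
    def cycles(self) -> np.ndarray:
        return self.curve.cycles


@dataclass
class EfficiencyEstimate:
    """Per-reaction efficiency, fit quality and quantitation cycles."""

    well_id: str
    target: str
    sample: str
    efficiency: float
    r_squared: float
    cq_regression: float | None
    cq_threshold: float | None
    window: tuple[int, int]
    flags: set[str] = field(default_factory=set)

    @property
    def cq(self) -> float | None:
        """Regression Cq, the primary per-reaction quantitation cycle."""
        return self.cq_regression


@dataclass
class AmpliconEfficiencySummary:
    target: str
    mean_efficiency: float
    n_reactions: int
    n_excluded: int
    mean_r_squared: float


def correct_baseline(
    curve: AmplificationCurve,
    baseline_cycles: tuple[int, int] | None = (3, 15),
    noise_band: float = 3.0,
    refine: bool = False,
) -> CorrectedCurve:
    """Subtract a constant baseline estimate from an amplification curve.

    The baseline defaults to the mean fluorescence over early cycles 3-15
    (the common instrument automatic-baseline window).  With ``refine=True``
    the constant is re-fitted to maximize the linearity (R^2) of the best
    log-linear window on the corrected curve, which removes the bias the
    early-cycle mean picks up from the growing exponential.  With
    ``baseline_cycles=None`` no subtraction is performed (already-corrected
    input).

    A curve whose maximum never exceeds the baseline plus ``noise_band``
    early-cycle standard deviations is flagged non-amplifying and should be
    excluded downstream.
    """
    f = curve.fluorescence
    if baseline_cycles is None:
        return CorrectedCurve(curve, f.copy(), 0.0, amplified=bool(np.ptp(f) > 0))
    lo, hi = baseline_cycles
    if hi - lo + 1 < 2:
        raise ValueError("baseline window needs at least 2 cycles")
    if curve.n_cycles < hi:
        hi = curve.n_cycles
    seg = f[lo - 1 : hi]
    base = float(np.mean(seg))
    noise = float(np.std(seg, ddof=1))
    amplified = bool(np.max(f) > base + noise_band * max(noise, 1e-12))
    if refine and amplified:
        base = _refine_baseline(f, base)
    return CorrectedCurve(curve, f - base, base, amplified)


def _refine_baseline(f: np.ndarray, base0: float) -> float:
    """Pick the constant whose subtraction maximizes best-window linearity.

    The true constant background can be no larger than the curve minimum
    and the early-cycle mean ``base0`` over-estimates it (the mean includes
    the growing exponential), so the search is confined to that narrow
    bracket; a wide search would let the optimizer chase spuriously linear
    stretches of the plateau instead.
    """
    fmin = float(np.min(f))
    lo = fmin - 2.0 * max(base0 - fmin, 1e-12)
    hi = base0

    def misfit(b: float) -> float:
        corr = f - b
        try:
            win = window_of_linearity_array(corr)
        except ValueError:
            return 1.0
        return 1.0 - _window_r2(corr, win)

    res = optimize.minimize_scalar(
        misfit, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * max(abs(base0), 1.0)},
    )
    return float(res.x) if res.fun < misfit(base0) else base0


def _window_r2(corrected: np.ndarray, window: tuple[int, int]) -> float:
    lo, hi = window
    y = np.log10(corrected[lo - 1 : hi])
    x = np.arange(lo, hi + 1, dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def window_of_linearity(
    corrected: CorrectedCurve,
    points: int = 4,
    plateau_fraction: float = 0.9,
) -> tuple[int, int]:
    """Find the ``points``-cycle window maximizing log-linearity.

    Candidate windows are contiguous runs of ``points`` cycles whose
    corrected fluorescence is strictly positive and monotonically
    increasing (the strictly continuous log-linear phase) and which lie
    below the plateau onset (no value above ``plateau_fraction`` of the
    curve maximum).  Among candidates the window with the largest R^2 of
    log10(fluorescence) versus cycle wins; ties break toward earlier
    cycles.
    """
    if not corrected.amplified:
        raise ValueError(f"well {corrected.curve.well_id}: non-amplifying curve")
    return window_of_linearity_array(corrected.corrected, points, plateau_fraction)


def window_of_linearity_array(
    corrected: np.ndarray, points: int = 4, plateau_fraction: float = 0.9
) -> tuple[int, int]:
    """:func:`window_of_linearity` on a bare corrected-fluorescence array."""
    if points < 3:
        raise ValueError("window needs at least 3 points")
    n = corrected.size
    ceiling = plateau_fraction * float(np.max(corrected))
    best: tuple[int, int] | None = None
    best_r2 = -np.inf
    for start in range(0, n - points + 1):
        seg = corrected[start : start + points]
        if np.any(seg <= 0) or np.any(np.diff(seg) <= 0) or np.any(seg > ceiling):
            continue
        y = np.log10(seg)
        x = np.arange(start + 1, start + points + 1, dtype=float)
        r = np.corrcoef(x, y)[0, 1]
        r2 = r * r
        if r2 > best_r2 + 1e-12:  # strict improvement; ties keep earlier window
            best_r2 = r2
            best = (start + 1, start + points)
    if best is None:
        raise ValueError("no usable window: fewer than `points` positive increasing cycles")
    return best


def reaction_efficiency_and_cq(
    corrected: CorrectedCurve,
    window: tuple[int, int] | None = None,
    threshold: float = 0.1,
    points: int = 4,
    min_r_squared: float | None = 0.998,
) -> EfficiencyEstimate:
    """Estimate per-reaction efficiency and both Cq variants.

    ``E = 10**slope`` from regressing log10(corrected fluorescence) on cycle
    within the window of linearity.  The regression Cq is the fractional
    cycle where the fitted line crosses ``log10(threshold)``; the
    fixed-threshold Cq interpolates log-fluorescence between the two cycles
    bracketing the threshold.  A non-positive slope flags a failed reaction;
    a threshold never crossed leaves the fixed-threshold Cq missing.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    c = corrected.curve
    flags: set[str] = set()
    if not corrected.amplified:
        return EfficiencyEstimate(
            c.well_id, c.target, c.sample, float("nan"), float("nan"),
            None, None, (0, 0), {FLAG_NON_AMPLIFYING},
        )
    if window is None:
        window = window_of_linearity(corrected, points=points)
    lo, hi = window
    y = np.log10(corrected.corrected[lo - 1 : hi])
    x = np.arange(lo, hi + 1, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    if slope <= 0:
        flags.add(FLAG_FAILED)
        return EfficiencyEstimate(
            c.well_id, c.target, c.sample, float("nan"), r2, None, None, window, flags
        )
    eff = float(10.0 ** slope)
    cq_reg = float((np.log10(threshold) - intercept) / slope)

    cq_thr = _threshold_cq(corrected.corrected, threshold)

    if not _has_plateau(corrected.corrected):
        flags.add(FLAG_NO_PLATEAU)
    if min_r_squared is not None and r2 < min_r_squared:
        flags.add(FLAG_BELOW_R2)
    return EfficiencyEstimate(
        c.well_id, c.target, c.sample, eff, r2, cq_reg, cq_thr, window, flags
    )


def _threshold_cq(corrected: np.ndarray, threshold: float) -> float | None:
    """Fractional cycle of the first upward threshold crossing (log scale)."""
    above = corrected >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))  # first cycle index (0-based) at/above threshold
    if k == 0:
        return 1.0
    f0, f1 = corrected[k - 1], corrected[k]
    if f0 <= 0:
        return float(k + 1)
    frac = (np.log10(threshold) - np.log10(f0)) / (np.log10(f1) - np.log10(f0))
    return float(k + frac)  # cycles are 1-based: previous cycle is k


def _has_plateau(corrected: np.ndarray, tail: int = 5, max_rel_rise: float = 0.05) -> bool:
    """A reaction plateaus when its last ``tail`` cycles have stopped rising.

    The criterion is the average per-cycle relative increase over the tail:
    above ``max_rel_rise`` the reaction is still in exponential/linear growth
    and is flagged ``no_plateau``.
    """
    if corrected.size < tail + 1:
        return False
    seg = corrected[-(tail + 1) :]
    top = float(np.max(np.abs(seg)))
    if top <= 0:
        return True
    rel = np.diff(seg) / top
    return bool(np.mean(rel) <= max_rel_rise)


def estimate_efficiencies(
    curves: Iterable[AmplificationCurve],
    baseline_cycles: tuple[int, int] | None = (3, 15),
    refine_baseline: bool = False,
    points: int = 4,
    threshold: float = 0.1,
    min_r_squared: float | None = 0.998,
) -> list[EfficiencyEstimate]:
    """Run the full per-well pipeline over many curves.

    Non-amplifying or failed wells are returned with their flags set rather
    than dropped, so callers can account for exclusions.
    """
    out = []
    for curve in curves:
        corr = correct_baseline(curve, baseline_cycles, refine=refine_baseline)
        if not corr.amplified:
            out.append(EfficiencyEstimate(
                curve.well_id, curve.target, curve.sample, float("nan"),
                float("nan"), None, None, (0, 0), {FLAG_NON_AMPLIFYING},
            ))
            continue
        try:
            est = reaction_efficiency_and_cq(
                corr, threshold=threshold, points=points, min_r_squared=min_r_squared
            )
        except ValueError:
            est = EfficiencyEstimate(
                curve.well_id, curve.target, curve.sample, float("nan"),
                float("nan"), None, None, (0, 0), {FLAG_FAILED},
            )
        out.append(est)
    return out


def flag_efficiency_outliers(
    estimates: Sequence[EfficiencyEstimate], mad_multiplier: float = 3.0
) -> None:
    """Mark estimates whose E deviates from the per-target median by more
    than ``mad_multiplier`` median absolute deviations (in place)."""
    by_target: dict[str, list[EfficiencyEstimate]] = {}
    for e in estimates:
        if np.isfinite(e.efficiency):
            by_target.setdefault(e.target, []).append(e)
    for target, group in by_target.items():
        effs = np.array([e.efficiency for e in group])
        med = np.median(effs)
        mad = np.median(np.abs(effs - med))
        if mad == 0:
            continue
        for e in group:
            if abs(e.efficiency - med) > mad_multiplier * mad:
                e.flags.add(FLAG_EFFICIENCY_OUTLIER)


def amplicon_efficiency_summary(
    estimates: Sequence[EfficiencyEstimate],
    include_outliers: bool = True,
) -> AmpliconEfficiencySummary:
    """Mean efficiency for one amplicon under the exclusion policy.

    Reactions flagged non-amplifying, failed or ``no_plateau`` are always
    excluded.  Efficiency outliers are included by default (the reference
    policy); set ``include_outliers=False`` to drop them too.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates supplied")
    targets = {e.target for e in estimates}
    if len(targets) != 1:
        raise ValueError(f"estimates span multiple targets: {sorted(targets)}")
    kept = []
    for e in estimates:
        if e.flags & {FLAG_NON_AMPLIFYING, FLAG_FAILED, FLAG_NO_PLATEAU}:
            continue
        if not include_outliers and FLAG_EFFICIENCY_OUTLIER in e.flags:
            continue
        kept.append(e)
    if not kept:
        raise ValueError("all reactions excluded by policy")
    return AmpliconEfficiencySummary(
        target=next(iter(targets)),
        mean_efficiency=float(np.mean([e.efficiency for e in kept])),
        n_reactions=len(kept),
        n_excluded=len(estimates) - len(kept),
        mean_r_squared=float(np.mean([e.r_squared for e in kept])),
    )


@dataclass
class FactorComparison:
    target: str
    factor_levels: list[str]
    f_statistic: float
    p_value: float
    degenerate: bool = False


def compare_efficiency_by_factor(
    estimates: Sequence[EfficiencyEstimate],
    factor: Mapping[str, str],
) -> list[FactorComparison]:
    """One-way ANOVA of per-reaction efficiency across factor levels.

    ``factor`` maps well ids to a level (experimental day, group, tissue...).
    One test per amplicon; a degenerate amplicon (zero variance overall) is
    reported with ``F = 0, p = 1`` and flagged.
    """
    by_target: dict[str, dict[str, list[float]]] = {}
    for e in estimates:
        if not np.isfinite(e.efficiency) or e.well_id not in factor:
            continue
        by_target.setdefault(e.target, {}).setdefault(factor[e.well_id], []).append(
            e.efficiency
        )
    out = []
    for target, levels in by_target.items():
        groups = [np.asarray(v) for v in levels.values()]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError(
                f"amplicon {target}: need >= 2 levels with >= 2 observations each"
            )
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            out.append(FactorComparison(target, list(levels), 0.0, 1.0, degenerate=True))
            continue
        f, p = stats.f_oneway(*groups)
        out.append(FactorComparison(target, list(levels), float(f), float(p)))
    return out
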