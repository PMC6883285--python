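"""Synthetic Cq datasets and amplification curves with known ground truth.

The Cq generator draws, for every (sample, gene, technical replicate),

    Cq = baseline_cq[gene] + group_effect[gene, group(sample)]
         + loading[sample] + gene_noise[sample, gene] + replicate_noise

with all perturbations Gaussian on the Cq scale (multiplicative on the
quantity scale, the scale every stability statistic consumes).  The shared
per-sample loading term is exactly the perturbation the delta-Cq and
geNorm statistics are invariant to, so end-to-end invariance can be tested
against known truth.  The ground-truth record carries each gene's total
planted perturbation (noise SD, group-effect spread across samples and
replicate-averaging contribution combined) and the implied stability
ordering.

The curve generator produces 40-cycle fluorescence series
``F_c = baseline + saturate(F0 * E**c) + noise`` with a smooth hyperbolic
plateau knee, recording the true per-well efficiency and the analytic
threshold-crossing cycle.

The ``paper_like`` preset emulates a published evaluation of 11 candidate
normalizers (snoRNAs and snRNA U6) in 16 mice split into non-treated /
sham / spared-nerve-injury groups (5/6/5), technical duplicates, gene mean
Cq spanning ~18-32 cycles, a per-gene noise ladder from 0.10 to 0.60
cycles, loading SD 0.3, and a +0.8-cycle injury shift planted on one
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import AmplificationCurve, CqDataset


@dataclass
class GeneSpec:
    name: str
    baseline_cq: float
    noise_sd: float
    group_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class CurveConfig:
    """Per-amplicon amplification-curve parameters."""

    efficiencies: dict[str, float]       # gene -> E in (1, 2]
    f0: float = 1e-7                     # initial fluorescence (a.u.)
    baseline: float = 0.05               # constant background (a.u.)
    plateau: float | None = 3.0          # saturation ceiling; None = no plateau
    noise_sd: float = 0.0                # additive fluorescence noise (a.u.)
    cycles: int = 40


@dataclass
class SimulationConfig:
    n_per_group: dict[str, int]
    genes: list[GeneSpec]
    loading_sd: float = 0.3
    replicate_sd: float = 0.08
    n_replicates: int = 2
    seed: int = 0
    tissue: str = "synthetic"
    curve: CurveConfig | None = None

    def __post_init__(self) -> None:
        for spec in self.genes:
            if spec.noise_sd < 0:
                raise ValueError(f"gene {spec.name}: negative noise SD")
            for grp in spec.group_effects:
                if grp not in self.n_per_group:
                    raise ValueError(
                        f"gene {spec.name}: group effect for unknown group {grp!r}"
                    )
        if self.loading_sd < 0 or self.replicate_sd < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted, for validating recovery."""

    gene_specs: list[GeneSpec]
    loading: dict[str, float]                  # per-sample loading shift
    total_perturbation: dict[str, float]       # per-gene planted instability
    stability_order: list[str]                 # most stable first
    true_efficiency: dict[str, float] = field(default_factory=dict)    # per well
    true_threshold_cq: dict[str, float] = field(default_factory=dict)  # per well


def _total_perturbation(
    spec: GeneSpec, n_per_group: Mapping[str, int], replicate_sd: float, n_rep: int
) -> float:
    """SD of a gene's planted perturbation across aggregated sample Cq values.

    Combines the gene's own noise SD, the across-sample spread its group
    effects induce (population variance with group-size weights) and the
    residual replicate-averaging noise ``replicate_sd^2 / n_rep``.
    """
    n_total = sum(n_per_group.values())
    effects = np.array([
        spec.group_effects.get(g, 0.0) for g in n_per_group for _ in range(n_per_group[g])
    ])
    group_var = float(np.var(effects)) if n_total else 0.0
    return float(np.sqrt(spec.noise_sd ** 2 + group_var + replicate_sd ** 2 / n_rep))


def simulate_cq_dataset(config: SimulationConfig) -> tuple[CqDataset, GroundTruth]:
    """Generate a replicated Cq dataset plus its ground-truth record.

    Deterministic under a fixed ``config.seed``: the same configuration
    always yields a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[str] = []
    groups: dict[str, str] = {}
    for grp, n in config.n_per_group.items():
        for i in range(1, n + 1):
            name = f"{grp}_{i}"
            samples.append(name)
            groups[name] = grp

    n_s, n_g, n_r = len(samples), len(config.genes), config.n_replicates
    loading = rng.normal(0.0, config.loading_sd, size=n_s)
    gene_noise = rng.normal(0.0, 1.0, size=(n_s, n_g))
    rep_noise = rng.normal(0.0, config.replicate_sd, size=(n_s, n_g, n_r))

    rep = np.empty((n_s, n_g, n_r))
    for j, spec in enumerate(config.genes):
        for i, s in enumerate(samples):
            mean = (
                spec.baseline_cq
                + spec.group_effects.get(groups[s], 0.0)
                + loading[i]
                + spec.noise_sd * gene_noise[i, j]
            )
            rep[i, j, :] = mean + rep_noise[i, j, :]
    cq = rep.mean(axis=2)

    ds = CqDataset(
        samples=samples,
        genes=[g.name for g in config.genes],
        cq=cq,
        groups=groups,
        tissue=config.tissue,
        setting="common_threshold",
        replicate_cq=rep,
    )
    total = {
        spec.name: _total_perturbation(
            spec, config.n_per_group, config.replicate_sd, n_r
        )
        for spec in config.genes
    }
    order = sorted(total, key=lambda g: (total[g], g))
    truth = GroundTruth(
        gene_specs=list(config.genes),
        loading=dict(zip(samples, loading)),
        total_perturbation=total,
        stability_order=order,
    )
    return ds, truth


def simulate_amplification_curves(
    config: SimulationConfig,
    samples: Sequence[str] | None = None,
) -> tuple[list[AmplificationCurve], GroundTruth]:
    """Generate per-well fluorescence curves with known E and crossing cycle.

    One well per (gene, sample).  The exponential is saturated through a
    smooth hyperbola ``x / (1 + x / plateau)`` so late cycles level off
    without a kink; with ``plateau=None`` the pure exponential is kept
    (useful to exercise no-plateau flagging).
    """
    if config.curve is None:
        raise ValueError("config.curve is not set")
    cc = config.curve
    rng = np.random.default_rng(config.seed + 1)
    if samples is None:
        samples = [
            f"{grp}_{i}" for grp, n in config.n_per_group.items() for i in range(1, n + 1)
        ]
    cycles = np.arange(1, cc.cycles + 1)
    curves: list[AmplificationCurve] = []
    true_e: dict[str, float] = {}
    true_cq: dict[str, float] = {}
    for spec in config.genes:
        e = cc.efficiencies[spec.name]
        if not (1.0 < e <= 2.0):
            raise ValueError(f"gene {spec.name}: efficiency {e} outside (1, 2]")
        for s in samples:
            well = f"{spec.name}|{s}"
            signal = cc.f0 * np.power(e, cycles.astype(float))
            if cc.plateau is not None:
                signal = signal / (1.0 + signal / cc.plateau)
            noise = rng.normal(0.0, cc.noise_sd, size=cycles.size) if cc.noise_sd else 0.0
            fl = cc.baseline + signal + noise
            curves.append(AmplificationCurve(well, spec.name, s, fl))
            true_e[well] = e
            true_cq[well] = float(np.log(0.1 / cc.f0) / np.log(e))
    truth = GroundTruth(
        gene_specs=list(config.genes),
        loading={},
        total_perturbation={},
        stability_order=[],
        true_efficiency=true_e,
        true_threshold_cq=true_cq,
    )
    return curves, truth


# --- presets ----------------------------------------------------------------

#: Candidate panel mirroring a published 11-assay evaluation: baseline mean
#: Cq (cycles) and per-gene noise SD (cycles); ladder 0.10..0.60 by 0.05.
PAPER_LIKE_GENES: list[tuple[str, float, float]] = [
    ("sno420", 24.0, 0.10),
    ("sno429", 23.0, 0.15),
    ("sno202", 18.4, 0.20),
    ("sno234", 25.5, 0.25),
    ("sno412", 31.6, 0.30),
    ("U6", 19.6, 0.35),
    ("sno142", 26.5, 0.40),
    ("sno251", 27.5, 0.45),
    ("sno55", 28.5, 0.50),
    ("sno292", 29.5, 0.55),
    ("sno135", 30.5, 0.60),
]

#: Gene carrying a planted +0.8-cycle injury shift in the preset.
PAPER_LIKE_SHIFTED_GENE = "sno292"
PAPER_LIKE_SHIFT = 0.8


def paper_like_config(seed: int = 0, with_curves: bool = False) -> SimulationConfig:
    """The default study-condition preset: 11 candidates, groups 5/6/5,
    duplicates, noise ladder 0.10-0.60, loading SD 0.3 and a +0.8-cycle
    injury (SNI) shift on one candidate."""
    genes = [
        GeneSpec(
            name,
            baseline,
            noise,
            group_effects={"SNI": PAPER_LIKE_SHIFT} if name == PAPER_LIKE_SHIFTED_GENE else {},
        )
        for name, baseline, noise in PAPER_LIKE_GENES
    ]
    curve = None
    if with_curves:
        rng = np.random.default_rng(seed + 2)
        effs = {
            name: float(rng.uniform(1.75, 1.95)) for name, _, _ in PAPER_LIKE_GENES
        }
        curve = CurveConfig(efficiencies=effs, f0=1e-7, baseline=0.05,
                            plateau=3.0, noise_sd=0.002, cycles=40)
    return SimulationConfig(
        n_per_group={"non-treated": 5, "sham": 6, "SNI": 5},
        genes=genes,
        loading_sd=0.3,
        replicate_sd=0.08,
        n_replicates=2,
        seed=seed,
        tissue="DRG-like",
        curve=curve,
    )
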