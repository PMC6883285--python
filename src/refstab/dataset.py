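"""Shared data model for Cq tables and raw amplification curves.

A :class:`CqDataset` holds a samples x genes matrix of quantitation-cycle
(Cq) values with per-sample experimental-group labels, optionally keeping
the pre-aggregation technical replicates as a third axis.  An
:class:`AmplificationCurve` is one well's fluorescence readings over PCR
cycles, annotated with its target assay and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Cq values outside this open interval are treated as invalid.
CQ_RANGE = (0.0, 45.0)

COMMON_THRESHOLD = "common_threshold"
REGRESSION_CORRECTED = "regression_corrected"


@dataclass
class CqDataset:
    """Samples x candidate-genes Cq matrix with group labels.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``cq``).
    genes
        Ordered candidate-gene identifiers (columns of ``cq``).
    cq
        ``(n_samples, n_genes)`` array of Cq values in cycles.  When
        ``replicate_cq`` is present this must equal its replicate mean.
    groups
        Mapping from sample identifier to experimental-group label
        (e.g. ``non-treated`` / ``sham`` / ``SNI``).
    tissue
        Free-form tissue label (e.g. ``DRG``, ``dhSC``, ``mPFC``).
    setting
        Cq-extraction provenance: ``common_threshold`` for a fixed
        fluorescence threshold, ``regression_corrected`` for
        window-of-linearity regression Cq values.
    replicate_cq
        Optional ``(n_samples, n_genes, n_replicates)`` array of
        technical-replicate Cq values before aggregation; missing
        replicates are NaN.
    """

    samples: list[str]
    genes: list[str]
    cq: np.ndarray
    groups: dict[str, str]
    tissue: str = ""
    setting: str = COMMON_THRESHOLD
    replicate_cq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.genes = list(self.genes)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.cq.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"cq shape {self.cq.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if self.replicate_cq is not None:
            self.replicate_cq = np.asarray(self.replicate_cq, dtype=float)
            if self.replicate_cq.shape[:2] != self.cq.shape:
                raise ValueError("replicate_cq leading axes must match cq")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def group_vector(self) -> np.ndarray:
        """Group label per sample, aligned with ``samples``."""
        return np.array([self.groups[s] for s in self.samples], dtype=object)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def gene_cq(self, gene: str) -> np.ndarray:
        return self.cq[:, self.gene_index(gene)]

    # -- derivation ----------------------------------------------------------

    def subset_genes(self, keep: Sequence[str]) -> "CqDataset":
        """New dataset restricted to ``keep`` (order taken from ``keep``)."""
        idx = [self.gene_index(g) for g in keep]
        rep = self.replicate_cq[:, idx, :] if self.replicate_cq is not None else None
        return replace(
            self,
            genes=list(keep),
            cq=self.cq[:, idx].copy(),
            replicate_cq=rep,
        )

    def subset_samples(self, keep: Sequence[str]) -> "CqDataset":
        idx = [self.samples.index(s) for s in keep]
        rep = self.replicate_cq[idx, :, :] if self.replicate_cq is not None else None
        return replace(
            self,
            samples=list(keep),
            cq=self.cq[idx, :].copy(),
            groups={s: self.groups[s] for s in keep},
            replicate_cq=rep,
        )

    def validate(self) -> list[str]:
        """Check dataset invariants; return one message per violation."""
        return validate_dataset(self)


@dataclass
class AmplificationCurve:
    """One well's raw fluorescence readings over cycles 1..C."""

    well_id: str
    target: str
    sample: str
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 1:
            raise ValueError("fluorescence must be a 1-D series")
        if self.n_cycles < 10:
            raise ValueError("amplification curve needs at least 10 cycles")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError(f"well {self.well_id}: non-finite fluorescence")

    @property
    def n_cycles(self) -> int:
        return self.fluorescence.size

    @property
    def cycles(self) -> np.ndarray:
        """Cycle indices 1..C."""
        return np.arange(1, self.n_cycles + 1)


def validate_dataset(ds: CqDataset) -> list[str]:
    """Report every CqDataset invariant violation with its location.

    An empty list means the dataset is valid.  This never raises: it is a
    reporting operation used both by the readers and by user-facing QC.
    """
    report: list[str] = []
    if len(set(ds.samples)) != len(ds.samples):
        report.append("duplicated sample identifiers")
    if len(set(ds.genes)) != len(ds.genes):
        report.append("duplicated gene identifiers")
    if not ds.groups:
        report.append("group map is empty")
    for s in ds.samples:
        if s not in ds.groups:
            report.append(f"sample {s!r} has no group label")
    lo, hi = CQ_RANGE
    for i, s in enumerate(ds.samples):
        for j, g in enumerate(ds.genes):
            v = ds.cq[i, j]
            if np.isnan(v):
                continue  # missing is allowed; downstream ops decide
            if not (lo < v < hi):
                report.append(f"Cq out of range at (sample={s}, gene={g}): {v}")
    if ds.replicate_cq is not None:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(ds.replicate_cq, axis=2)
        with np.errstate(invalid="ignore"):
            bad = ~np.isclose(means, ds.cq, equal_nan=True)
        for i, j in zip(*np.nonzero(bad)):
            report.append(
                f"cq does not equal replicate mean at "
                f"(sample={ds.samples[i]}, gene={ds.genes[j]})"
            )
    return report
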