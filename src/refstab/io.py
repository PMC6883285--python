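"""Readers and writers for Cq tables and raw amplification-curve tables.

Two delimited-text layouts are accepted for Cq data:

* **long** (canonical): one row per (sample, gene[, replicate]) with columns
  mapped through a schema dictionary, so arbitrary instrument export
  headers can be consumed without renaming files;
* **wide**: samples as rows, genes as columns, with optional ``group``
  column — a common spreadsheet layout for supplementary tables.

The delimiter is auto-detected among comma, tab and semicolon; the decimal
separator is fixed to ``.``.  ``Undetermined`` / empty wells are read as
missing (NaN), never as the cycle count.
"""

from __future__ import annotations

import csv
import io as _stdio
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import CQ_RANGE, AmplificationCurve, CqDataset

#: Default long-format column names, overridable via the ``schema`` map.
DEFAULT_SCHEMA = {
    "sample": "sample",
    "group": "group",
    "gene": "gene",
    "cq": "cq",
    "replicate": "replicate",
    "tissue": "tissue",
    "setting": "setting",
}

#: Cell contents treated as a missing Cq (case-insensitive).
MISSING_TOKENS = {"", "na", "nan", "undetermined", "no cq", "noct", "undet"}


class SchemaError(ValueError):
    """A declared column is absent from the file."""


class CqValidationError(ValueError):
    """A cell fails Cq validation; the message carries the row number."""


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _parse_cq(raw: object, row: int) -> float:
    if raw is None:
        return np.nan
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return np.nan
    try:
        value = float(text)
    except ValueError:
        raise CqValidationError(f"row {row}: non-numeric Cq value {text!r}") from None
    lo, hi = CQ_RANGE
    if not (lo < value < hi):
        raise CqValidationError(f"row {row}: Cq {value} outside ({lo}, {hi})")
    return value


def read_cq_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    layout: str = "long",
    tissue: str | None = None,
    setting: str | None = None,
) -> CqDataset:
    """Read a delimited Cq table into a validated :class:`CqDataset`.

    Parameters
    ----------
    path
        Delimited text file (comma, tab or semicolon separated).
    schema
        Maps the roles ``sample, group, gene, cq, replicate, tissue,
        setting`` to the file's column names; unmentioned roles keep
        their default names.
    layout
        ``"long"`` (one row per measurement) or ``"wide"`` (samples as
        rows, genes as columns; ``sample`` and optional ``group`` columns
        named through the schema).
    tissue, setting
        Override the corresponding labels; otherwise taken from the file
        columns when present.

    Row order never affects the result: samples and genes are ordered by
    first appearance in the file, replicate slots by replicate key.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]

    if layout == "wide":
        return _read_wide(df, cols, tissue=tissue, setting=setting)
    if layout != "long":
        raise ValueError(f"unknown layout {layout!r}")

    for role in ("sample", "gene", "cq"):
        if cols[role] not in df.columns:
            raise SchemaError(f"missing column {cols[role]!r} (role: {role})")
    has_group = cols["group"] in df.columns
    has_rep = cols["replicate"] in df.columns

    sample_col = df[cols["sample"]].astype(str)
    gene_col = df[cols["gene"]].astype(str)
    cq_vals = [_parse_cq(v, i + 2) for i, v in enumerate(df[cols["cq"]])]

    samples = list(dict.fromkeys(sample_col))
    genes = list(dict.fromkeys(gene_col))
    s_idx = {s: i for i, s in enumerate(samples)}
    g_idx = {g: i for i, g in enumerate(genes)}

    groups: dict[str, str] = {}
    if has_group:
        for row, (s, grp) in enumerate(zip(sample_col, df[cols["group"]].astype(str)), start=2):
            if s in groups and groups[s] != grp:
                raise CqValidationError(
                    f"row {row}: sample {s!r} has conflicting group labels "
                    f"{groups[s]!r} and {grp!r}"
                )
            groups[s] = grp
    else:
        groups = {s: "all" for s in samples}

    # replicate slot per (sample, gene): sort keys for a deterministic order
    if has_rep:
        rep_keys = sorted(dict.fromkeys(df[cols["replicate"]].astype(str)), key=_rep_sort_key)
        r_idx = {r: i for i, r in enumerate(rep_keys)}
        rep = np.full((len(samples), len(genes), len(rep_keys)), np.nan)
        seen: set[tuple[str, str, str]] = set()
        for row, (s, g, r, v) in enumerate(
            zip(sample_col, gene_col, df[cols["replicate"]].astype(str), cq_vals), start=2
        ):
            key = (s, g, r)
            if key in seen:
                raise CqValidationError(
                    f"row {row}: duplicated (sample, gene, replicate) = {key}"
                )
            seen.add(key)
            rep[s_idx[s], g_idx[g], r_idx[r]] = v
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cq = np.nanmean(rep, axis=2)
    else:
        rep = None
        cq = np.full((len(samples), len(genes)), np.nan)
        seen2: set[tuple[str, str]] = set()
        for row, (s, g, v) in enumerate(zip(sample_col, gene_col, cq_vals), start=2):
            key2 = (s, g)
            if key2 in seen2:
                raise CqValidationError(f"row {row}: duplicated (sample, gene) = {key2}")
            seen2.add(key2)
            cq[s_idx[s], g_idx[g]] = v

    tissue_val = tissue if tissue is not None else _single_label(df, cols["tissue"], "")
    setting_val = setting if setting is not None else _single_label(
        df, cols["setting"], "common_threshold"
    )
    return CqDataset(
        samples=samples, genes=genes, cq=cq, groups=groups,
        tissue=tissue_val, setting=setting_val, replicate_cq=rep,
    )


def _rep_sort_key(token: str):
    try:
        return (0, float(token), token)
    except ValueError:
        return (1, 0.0, token)


def _single_label(df: pd.DataFrame, col: str, default: str) -> str:
    if col in df.columns:
        labels = list(dict.fromkeys(df[col].astype(str)))
        if len(labels) > 1:
            raise CqValidationError(f"column {col!r} carries multiple labels: {labels}")
        return labels[0]
    return default


def _read_wide(
    df: pd.DataFrame,
    cols: Mapping[str, str],
    tissue: str | None,
    setting: str | None,
) -> CqDataset:
    if cols["sample"] not in df.columns:
        raise SchemaError(f"missing column {cols['sample']!r} (role: sample)")
    meta = {cols[r] for r in ("sample", "group", "tissue", "setting") if cols[r] in df.columns}
    genes = [c for c in df.columns if c not in meta]
    if not genes:
        raise SchemaError("wide layout: no gene columns found")
    samples = [str(s) for s in df[cols["sample"]]]
    if len(set(samples)) != len(samples):
        raise CqValidationError("wide layout: duplicated sample rows")
    cq = np.array(
        [[_parse_cq(df.iloc[i][g], i + 2) for g in genes] for i in range(len(df))]
    )
    if cols["group"] in df.columns:
        groups = {s: str(g) for s, g in zip(samples, df[cols["group"]])}
    else:
        groups = {s: "all" for s in samples}
    tissue_val = tissue if tissue is not None else _single_label(df, cols["tissue"], "")
    setting_val = setting if setting is not None else _single_label(
        df, cols["setting"], "common_threshold"
    )
    return CqDataset(
        samples=samples, genes=genes, cq=cq, groups=groups,
        tissue=tissue_val, setting=setting_val,
    )


def write_cq_table(ds: CqDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset in canonical long format (replicates expanded)."""
    rows = []
    for i, s in enumerate(ds.samples):
        for j, g in enumerate(ds.genes):
            base = {
                "sample": s,
                "group": ds.groups[s],
                "gene": g,
                "tissue": ds.tissue,
                "setting": ds.setting,
            }
            if ds.replicate_cq is not None:
                for r in range(ds.replicate_cq.shape[2]):
                    v = ds.replicate_cq[i, j, r]
                    if np.isnan(v):
                        continue
                    rows.append({**base, "replicate": r + 1, "cq": v})
            else:
                v = ds.cq[i, j]
                rows.append({**base, "cq": "" if np.isnan(v) else v})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_amplification_table(path: str | Path) -> list[AmplificationCurve]:
    """Read per-well fluorescence series from a delimited table.

    Expects columns ``well, target, sample, cycle, fluorescence``.  Rows may
    be in any order; cycles must form a contiguous 1..C run per well, and
    duplicated (well, cycle) pairs are rejected.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    for col in ("well", "target", "sample", "cycle", "fluorescence"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    curves: list[AmplificationCurve] = []
    for well, sub in df.groupby("well", sort=False):
        cycles = sub["cycle"].astype(int).to_numpy()
        if len(set(cycles)) != len(cycles):
            raise CqValidationError(f"well {well}: duplicated cycle index")
        order = np.argsort(cycles)
        cycles = cycles[order]
        if cycles[0] != 1 or not np.array_equal(cycles, np.arange(1, len(cycles) + 1)):
            raise CqValidationError(f"well {well}: cycles not contiguous from 1")
        fl = sub["fluorescence"].astype(float).to_numpy()[order]
        target = str(sub["target"].iloc[0])
        sample = str(sub["sample"].iloc[0])
        curves.append(AmplificationCurve(str(well), target, sample, fl))
    return curves


def write_amplification_table(
    curves: Sequence[AmplificationCurve], path: str | Path, sep: str = ","
) -> None:
    rows = []
    for c in curves:
        for cyc, fl in zip(c.cycles, c.fluorescence):
            rows.append(
                {"well": c.well_id, "target": c.target, "sample": c.sample,
                 "cycle": cyc, "fluorescence": fl}
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
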