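"""Readers and normalization for expression matrices, signatures and clinical tables.

Formats: expression as TSV (identifiers in the first column, sample ids in the
header), gene sets as Broad-dialect GMT, clinical annotations as CSV with a
YAML/JSON schema mapping source columns and enum spellings onto the canonical
:class:`~regact.containers.ClinicalTable` fields.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    ProbesetMatrix,
    TargetSignature,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "collapse_probesets",
    "quantile_normalize",
    "median_center",
    "read_gmt",
    "write_gmt",
    "read_clinical_csv",
    "DEFAULT_VALUE_MAPS",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending row/column."""


def read_expression_tsv(
    path,
    id_kind: str = "gene",
    probeset_to_gene: Mapping[str, str] | None = None,
    channel: str = "one_channel",
) -> ExpressionMatrix | ProbesetMatrix:
    """Read a genes-or-probesets x samples TSV.

    The first column holds identifiers (header text is free), remaining
    columns are numeric with sample ids in the header. Blank cells become
    missing values; any other non-numeric cell is a :class:`ParseError`.
    """
    path = Path(path)
    if id_kind not in ("gene", "probeset"):
        raise ValueError(f"id_kind must be 'gene' or 'probeset', got {id_kind!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path.name}: header has no sample columns")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ParseError(f"{path.name}: duplicate sample column {s!r}")
        seen.add(s)

    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, skip_blank_lines=True
    )
    raw.columns = samples
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path.name}: duplicate row identifier {dup!r}")

    values = pd.DataFrame(index=raw.index.astype(str), columns=samples, dtype=float)
    for col in samples:
        s = raw[col].str.strip()
        num = pd.to_numeric(s.replace("", np.nan), errors="coerce")
        bad = s.ne("") & num.isna()
        if bad.any():
            row = s.index[bad][0]
            raise ParseError(
                f"{path.name}: non-numeric value {s[bad].iloc[0]!r} at row {row!r}, column {col!r}"
            )
        values[col] = num
    values.index.name = None
    logger.info("read %s: %d rows x %d samples", path.name, *values.shape)
    if id_kind == "probeset":
        return ProbesetMatrix(values, dict(probeset_to_gene or {}), channel=channel)
    return ExpressionMatrix(values, channel=channel)


def write_expression_tsv(m: ExpressionMatrix | ProbesetMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def collapse_probesets(m: ProbesetMatrix) -> ExpressionMatrix:
    """Collapse probesets to gene symbols, keeping the highest-mean probeset.

    For a gene measured by several probesets, the retained row is the probeset
    with the largest mean value across all samples; ties keep the first
    probeset in input order. Unmapped probesets are dropped.
    """
    if not m.probeset_to_gene:
        raise ValueError("probeset_to_gene mapping is empty")
    mapped = [p for p in m.values.index if p in m.probeset_to_gene]
    n_dropped = m.values.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probesets: dropped %d unmapped probesets", n_dropped)
    means = m.values.loc[mapped].mean(axis=1)
    best: dict[str, str] = {}  # gene -> probeset, first-wins on tied means
    for p in mapped:
        g = m.probeset_to_gene[p]
        if g not in best or means[p] > means[best[g]]:
            best[g] = p
    genes = list(best)  # insertion order: first appearance of each gene
    values = m.values.loc[[best[g] for g in genes]].copy()
    values.index = pd.Index(genes)
    logger.info("collapse_probesets: %d probesets -> %d genes", len(mapped), len(genes))
    return ExpressionMatrix(values, channel=m.channel)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the mean of the sorted columns.

    After the operation every column's sorted values equal the across-column
    mean of sorted values (identically, when the column has no ties); ranks
    within each column are preserved. Tied values within a column all receive
    the mean of the reference values at their tied rank positions. Calling on
    an already-normalized matrix is a no-op, making the operation idempotent.
    """
    if m.quantile_normalized:
        return m.with_values(m.values.copy())
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "matrix contains missing values; drop incomplete rows or impute before "
            "quantile normalization"
        )
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        o = order[:, j]
        vals = X[o, j]
        starts = np.flatnonzero(np.r_[True, vals[1:] != vals[:-1]])
        counts = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(ref, starts) / counts
        out[o, j] = np.repeat(group_means, counts)
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        quantile_normalized=True,
    )


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene row to median 0 across samples.

    Converts one-channel intensities into relative expression comparable to
    two-channel log-ratios before rank-based scoring. Requires quantile
    normalization first. A short fixed-point iteration absorbs the occasional
    one-ulp residual that a single subtraction can leave on even-length rows.
    """
    if not m.quantile_normalized:
        raise ValueError("median_center requires a quantile-normalized matrix")
    X = m.values.to_numpy(dtype=float).copy()
    for _ in range(4):
        med = np.median(X, axis=1, keepdims=True)
        if not med.any():
            break
        X -= med
    return m.with_values(
        pd.DataFrame(X, index=m.values.index, columns=m.values.columns),
        median_centered=True,
    )


def read_gmt(path) -> list[TargetSignature]:
    """Read gene sets from a GMT file (name TAB description TAB gene...)."""
    path = Path(path)
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >=3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes in %r de-duplicated", path.name, lineno, name)
            signatures.append(TargetSignature(name, genes))
    logger.info("read %s: %d signatures", path.name, len(signatures))
    return signatures


def write_gmt(signatures, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


#: Case-insensitive spellings accepted for enum-valued clinical fields.
DEFAULT_VALUE_MAPS: dict[str, dict[str, object]] = {
    "response": {"pcr": "pCR", "rd": "RD"},
    "rcb_class": {
        "rcb0": "RCB0", "rcb-0": "RCB0", "0": "RCB0",
        "rcb1": "RCB1", "rcb-1": "RCB1", "rcb-i": "RCB1", "i": "RCB1", "1": "RCB1",
        "rcb2": "RCB2", "rcb-2": "RCB2", "rcb-ii": "RCB2", "ii": "RCB2", "2": "RCB2",
        "rcb3": "RCB3", "rcb-3": "RCB3", "rcb-iii": "RCB3", "iii": "RCB3", "3": "RCB3",
    },
    "er": {"positive": "positive", "pos": "positive", "+": "positive", "1": "positive",
           "negative": "negative", "neg": "negative", "-": "negative", "0": "negative"},
    "nodal": {"positive": "positive", "pos": "positive", "1": "positive",
              "negative": "negative", "neg": "negative", "0": "negative"},
    "drfs_event": {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False},
}
DEFAULT_VALUE_MAPS["pr"] = DEFAULT_VALUE_MAPS["er"]
DEFAULT_VALUE_MAPS["her2"] = DEFAULT_VALUE_MAPS["er"]

_NUMERIC_FIELDS = ("stage", "grade", "age", "drfs_time")


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        text = Path(schema).read_text()
        return yaml.safe_load(text) if str(schema).endswith((".yaml", ".yml")) else json.loads(text)
    return dict(schema)


def read_clinical_csv(path, schema=None) -> ClinicalTable:
    """Read a clinical CSV into the canonical table.

    ``schema`` (dict or YAML/JSON path) may declare ``sample_id`` (source
    column name, default ``sample_id``), ``columns`` (canonical field ->
    source column) and ``values`` (field -> {spelling: canonical value},
    merged over :data:`DEFAULT_VALUE_MAPS`). Enum cells are matched
    case-insensitively; unparseable cells become missing and are counted.
    """
    path = Path(path)
    schema = _load_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_col = schema.get("sample_id", "sample_id")
    if id_col not in raw.columns:
        raise ParseError(f"{path.name}: sample-id column {id_col!r} not found")
    colmap = {f: schema.get("columns", {}).get(f, f) for f in CLINICAL_COLUMNS}
    out = pd.DataFrame(index=pd.Index(raw[id_col].str.strip(), name="sample_id"))
    n_unparsed = 0
    for f in CLINICAL_COLUMNS:
        src = colmap[f]
        if src not in raw.columns:
            out[f] = np.nan
            continue
        cells = raw[src].str.strip()
        if f in _NUMERIC_FIELDS:
            parsed = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
            n_unparsed += int((cells.ne("") & parsed.isna()).sum())
            out[f] = parsed.to_numpy()
        else:
            vmap = {**DEFAULT_VALUE_MAPS.get(f, {}), **schema.get("values", {}).get(f, {})}
            vmap = {str(k).lower(): v for k, v in vmap.items()}
            parsed = cells.str.lower().map(vmap)
            n_unparsed += int((cells.ne("") & parsed.isna()).sum())
            out[f] = parsed.to_numpy()
    if n_unparsed:
        logger.info("read %s: %d unparseable cells recorded as missing", path.name, n_unparsed)
    logger.info("read %s: %d samples", path.name, len(out))
    return ClinicalTable(out)
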