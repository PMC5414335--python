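"""Shared in-memory containers for expression data, signatures and clinical tables.

The canonical orientation for expression data is genes (or probesets) in rows
and samples in columns, matching how processed microarray matrices are
distributed. Estimator classes accept the transposed samples x genes
:class:`pandas.DataFrame` (scikit-learn orientation); use
:meth:`ExpressionMatrix.to_samples_by_genes` to convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbesetMatrix",
    "ClinicalTable",
    "TargetSignature",
    "CLINICAL_COLUMNS",
]

#: Canonical clinical columns; readers fill missing ones with NA.
CLINICAL_COLUMNS = (
    "response",
    "rcb_class",
    "er",
    "pr",
    "her2",
    "stage",
    "grade",
    "age",
    "nodal",
    "subtype",
    "drfs_time",
    "drfs_event",
)

RESPONSE_LEVELS = ("pCR", "RD")
RCB_LEVELS = ("RCB0", "RCB1", "RCB2", "RCB3")
STATUS_LEVELS = ("positive", "negative")


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes x samples, with provenance flags.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index and sample ids as columns.
    channel
        ``"one_channel"`` (intensities, e.g. Affymetrix) or ``"two_channel"``
        (log-ratios, e.g. Agilent). One-channel data should be median centered
        per gene after quantile normalization before rank-based scoring.
    quantile_normalized, median_centered
        Provenance flags set by the normalization operations.
    """

    values: pd.DataFrame
    channel: str = "one_channel"
    quantile_normalized: bool = False
    median_centered: bool = False

    def __post_init__(self) -> None:
        if self.channel not in ("one_channel", "two_channel"):
            raise ValueError(f"unknown channel {self.channel!r}")
        _check_unique(self.values.index, "gene symbols")
        _check_unique(self.values.columns, "sample ids")

    @property
    def gene_symbols(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Return the samples x genes view used by the estimator API."""
        return self.values.T

    def with_values(self, values: pd.DataFrame, **flags) -> "ExpressionMatrix":
        return replace(self, values=values, **flags)


@dataclass
class ProbesetMatrix:
    """Probeset-level matrix plus probeset -> gene-symbol mapping.

    The mapping may be many-to-one (several probesets per gene) and partial
    (unmapped probesets are dropped at collapse time).
    """

    values: pd.DataFrame  # probesets x samples
    probeset_to_gene: Mapping[str, str] = field(default_factory=dict)
    channel: str = "one_channel"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probeset ids")
        _check_unique(self.values.columns, "sample ids")

    @property
    def probeset_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with a fixed canonical schema.

    ``data`` is indexed by sample id; any canonical column absent from the
    source is present and entirely missing. Enum-valued columns hold the
    canonical strings (``pCR``/``RD``, ``positive``/``negative``, ``RCB0``..)
    with ``NaN`` for missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            self.data = self.data.copy()
            for c in missing:
                self.data[c] = np.nan
        bad = set(self.data["response"].dropna()) - set(RESPONSE_LEVELS)
        if bad:
            raise ValueError(f"response values outside {RESPONSE_LEVELS}: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class TargetSignature:
    """A named binary set of target gene symbols.

    Genes are stored as a sorted tuple so equal sets compare equal and
    iteration order is deterministic regardless of input order.
    """

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Iterable[str]):
        cleaned = sorted({g.strip() for g in genes if g and g.strip()})
        if not cleaned:
            raise ValueError(f"signature {name!r} has no genes")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)
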