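"""Tabular I/O and peptide→gene aggregation for PhIP-seq count data.

A PhIP-seq experiment produces, per sample, read counts for every peptide in
the phage-display library.  Downstream statistics operate at the gene level,
so the entry points here are: read a delimited count matrix (features ×
samples), validate it, and sum all peptide counts mapping to the same gene.

Conventions
-----------
* Tab-separated is the canonical dialect; comma-separated files are accepted.
  The first column holds the feature identifier, the header row is mandatory.
* Feature and sample identifiers are case-sensitive opaque strings.
* Counts are nonnegative integers; negative or non-numeric cells are hard
  errors reported with row/column coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_LEVELS = ("peptide", "gene")
VALID_ROLES = ("case", "control", "mock_ip")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Nonnegative integer read counts, features × samples.

    Parameters
    ----------
    counts
        DataFrame with feature ids as the index and sample ids as columns.
    level
        ``"peptide"`` or ``"gene"``.
    """

    counts: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise ValidationError(f"level must be one of {VALID_LEVELS}, got {self.level!r}")
        validate_counts_frame(self.counts)
        empty = self.counts.columns[self.counts.sum(axis=0).to_numpy() == 0]
        if len(empty):
            logger.warning("samples with zero total reads: %s", list(empty))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def validate_counts_frame(df: pd.DataFrame) -> None:
    dup_feat = df.index[df.index.duplicated()].unique()
    if len(dup_feat):
        raise ValidationError(f"duplicate feature ids: {list(dup_feat)}")
    dup_samp = df.columns[df.columns.duplicated()].unique()
    if len(dup_samp):
        raise ValidationError(f"duplicate sample ids: {list(dup_samp)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = _first_bad_cell(df, lambda v: not _is_number(v))
        raise ValidationError(f"non-numeric count at feature {bad[0]!r}, sample {bad[1]!r}")
    if np.isnan(values.astype(float)).any():
        bad = _first_bad_cell(df, lambda v: pd.isna(v))
        raise ValidationError(f"missing count at feature {bad[0]!r}, sample {bad[1]!r}")
    if (values < 0).any():
        bad = _first_bad_cell(df, lambda v: v < 0)
        raise ValidationError(f"negative count at feature {bad[0]!r}, sample {bad[1]!r}")
    if not np.allclose(values, np.round(values.astype(float))):
        bad = _first_bad_cell(df, lambda v: float(v) != round(float(v)))
        raise ValidationError(f"non-integral count at feature {bad[0]!r}, sample {bad[1]!r}")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_bad_cell(df: pd.DataFrame, pred) -> tuple[str, str]:
    for f in df.index:
        for s in df.columns:
            try:
                if pred(df.at[f, s]):
                    return str(f), str(s)
            except TypeError:
                return str(f), str(s)
    raise AssertionError("no offending cell found")  # pragma: no cover


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_count_matrix(path: str | Path, level: str) -> CountMatrix:
    """Read a delimited count matrix (first column = feature id, header row)."""
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:  # pandas would silently mangle duplicate headers
        raise ValidationError(f"duplicate sample ids: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    validate_counts_frame(df)
    return CountMatrix(counts=df.astype(np.int64), level=level)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV, feature ids in the first column."""
    df = cm.counts.copy()
    df.index.name = cm.level
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Peptide → gene map
# ---------------------------------------------------------------------------

@dataclass
class PeptideGeneMap:
    """One-gene-per-peptide mapping (peptide_id → gene_id)."""

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PeptideGeneMap":
        mapping: dict[str, str] = {}
        for pep, gene in pairs:
            pep, gene = str(pep), str(gene)
            if pep in mapping and mapping[pep] != gene:
                raise ValidationError(
                    f"peptide {pep!r} maps to both {mapping[pep]!r} and {gene!r}"
                )
            mapping[pep] = gene
        return cls(mapping)

    def __getitem__(self, peptide_id: str) -> str:
        return self.mapping[peptide_id]

    def __len__(self) -> int:
        return len(self.mapping)


def read_peptide_gene_map(path: str | Path) -> PeptideGeneMap:
    """Read a two-column TSV (peptide_id, gene_id)."""
    df = pd.read_csv(path, sep=_detect_sep(Path(path)))
    if df.shape[1] < 2:
        raise ValidationError("peptide→gene map needs two columns (peptide_id, gene_id)")
    pep_col, gene_col = df.columns[:2]
    return PeptideGeneMap.from_pairs(zip(df[pep_col].astype(str), df[gene_col].astype(str)))


def write_peptide_gene_map(pmap: PeptideGeneMap, path: str | Path) -> None:
    pd.DataFrame(
        {"peptide_id": list(pmap.mapping), "gene_id": list(pmap.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Per-sample role (case / control / mock_ip), cohort label and metadata."""

    table: pd.DataFrame  # index sample_id; columns: role, cohort, free metadata

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = list(t.index[t.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in sample sheet: {dups}")
        bad = sorted(set(t["role"]) - set(VALID_ROLES))
        if bad:
            raise ValidationError(f"unknown roles {bad}; allowed: {VALID_ROLES}")

    def _ids(self, role: str) -> list[str]:
        return list(self.table.index[self.table["role"] == role])

    @property
    def case_ids(self) -> list[str]:
        return self._ids("case")

    @property
    def control_ids(self) -> list[str]:
        return self._ids("control")

    @property
    def mock_ids(self) -> list[str]:
        return self._ids("mock_ip")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def role_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "role"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())

    @classmethod
    def from_roles(
        cls,
        roles: Mapping[str, str],
        cohort: str | Mapping[str, str] = "default",
    ) -> "SampleSheet":
        ids = list(roles)
        cohorts = (
            [cohort] * len(ids) if isinstance(cohort, str) else [cohort[s] for s in ids]
        )
        df = pd.DataFrame({"role": [roles[s] for s in ids], "cohort": cohorts},
                          index=pd.Index(ids, name="sample_id"))
        return cls(df)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV with columns sample_id, role, cohort (+ free metadata)."""
    df = pd.read_csv(path, sep=_detect_sep(Path(path)))
    required = {"sample_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if "cohort" not in df.columns:
        df["cohort"] = "default"
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_to_gene(
    pep: CountMatrix, pmap: PeptideGeneMap, drop_unmapped: bool = False
) -> CountMatrix:
    """Sum all peptide counts mapping to the same gene.

    Gene order is the order of first appearance among the (kept) peptides.
    Per-sample totals are conserved exactly when no peptide is dropped.

    Raises
    ------
    ValidationError
        If ``pep`` is not peptide-level, or peptides are unmapped and
        ``drop_unmapped`` is False.
    """
    if pep.level != "peptide":
        raise ValidationError("aggregate_to_gene expects a peptide-level CountMatrix")
    unmapped = [p for p in pep.feature_ids if p not in pmap.mapping]
    if unmapped:
        if not drop_unmapped:
            raise ValidationError(
                f"{len(unmapped)} peptide(s) have no gene mapping: {unmapped[:10]}"
                + (" ..." if len(unmapped) > 10 else "")
            )
        logger.info("dropping %d unmapped peptide(s)", len(unmapped))
    kept = pep.counts.drop(index=unmapped)
    genes = pd.Index([pmap[p] for p in kept.index], name="gene")
    agg = kept.groupby(genes, sort=False).sum()
    return CountMatrix(counts=agg.astype(np.int64), level="gene")
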