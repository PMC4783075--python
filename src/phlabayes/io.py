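"""Reading and writing the cohort CSV dialect and result tables.

The input is one CSV row per subject.  Columns are classified by content,
not by name or position: a column whose every value is an integer in
{0, 1, 2} is an HLA copy-number column; a column whose values are all
TRUE/FALSE (case-insensitive, blanks allowed for missing ELISpots) is a
peptide outcome column; at most one remaining column of unique strings is
taken as subject identifiers.  '*' is not allowed in column names (HLA
names use '_' instead, e.g. DRB1_15_01 for DRB1*15:01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "InputDialect",
    "sanitize_allele_name",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_manifest",
]

_INT_VALUES = {"0", "1", "2"}
_BOOL_TRUE = {"true"}
_BOOL_FALSE = {"false"}


@dataclass(frozen=True)
class InputDialect:
    """Optional explicit column roles, overriding content classification."""

    hla_columns: tuple[str, ...] = ()
    peptide_columns: tuple[str, ...] = ()
    id_column: str | None = None
    missing_values: tuple[str, ...] = field(default=("", "na", "nan"))


def sanitize_allele_name(name: str) -> str:
    """Map the HLA nomenclature separators '*' and ':' to '_'."""
    return name.replace("*", "_").replace(":", "_")


def _classify(name: str, values: pd.Series, dialect: InputDialect) -> str:
    if name in dialect.hla_columns:
        return "hla"
    if name in dialect.peptide_columns:
        return "peptide"
    if name == dialect.id_column:
        return "id"
    stripped = values.str.strip()
    lowered = stripped.str.lower()
    if stripped.isin(_INT_VALUES).all():
        return "hla"
    if lowered.isin(_BOOL_TRUE | _BOOL_FALSE | set(dialect.missing_values)).all():
        return "peptide"
    return "other"


def read_cohort_csv(path, dialect: InputDialect | None = None) -> CohortTable:
    """Parse a cohort CSV into a validated :class:`CohortTable`.

    Column order is irrelevant; classification is by content (see module
    docstring) unless *dialect* pins specific columns.  Blank peptide cells
    become missing responses.  Raises with the offending column (and cell)
    on '*' in a name, on a column fitting neither class, and on a subject
    with all-zero copy numbers.
    """
    dialect = dialect or InputDialect()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for name in frame.columns:
        if "*" in name:
            raise ValueError(
                f"column name {name!r} contains '*'; replace '*' (and ':') with '_' "
                "in HLA column names, e.g. DRB1_15_01"
            )
    hla_cols, pep_cols, id_cols = [], [], []
    for name in frame.columns:
        kind = _classify(name, frame[name], dialect)
        if kind == "hla":
            hla_cols.append(name)
        elif kind == "peptide":
            pep_cols.append(name)
        elif kind == "id":
            id_cols.append(name)
        else:
            if not id_cols and frame[name].is_unique:
                id_cols.append(name)
                continue
            stripped = frame[name].str.strip()
            bad_int = ~stripped.isin(_INT_VALUES)
            offending = stripped[bad_int].iloc[0] if bad_int.any() else stripped.iloc[0]
            raise ValueError(
                f"column {name!r} is neither an HLA copy-number column (0/1/2) nor a "
                f"TRUE/FALSE peptide column; offending cell value: {offending!r}"
            )
    if not hla_cols:
        raise ValueError("no HLA copy-number columns found")
    logger.info(
        "read %d subjects: %d HLA column(s), %d peptide column(s), id column: %s",
        len(frame), len(hla_cols), len(pep_cols), id_cols[0] if id_cols else "none",
    )
    copy_matrix = frame[hla_cols].apply(lambda c: c.str.strip()).astype(int).to_numpy()
    responses = pd.DataFrame(index=pd.RangeIndex(len(frame)))
    for pep in pep_cols:
        lowered = frame[pep].str.strip().str.lower()
        values = pd.array(
            [True if v in _BOOL_TRUE else False if v in _BOOL_FALSE else pd.NA for v in lowered],
            dtype="boolean",
        )
        responses[pep] = values
    subject_ids = (
        frame[id_cols[0]].astype(str).tolist()
        if id_cols
        else [f"S{i + 1:03d}" for i in range(len(frame))]
    )
    return CohortTable(
        subject_ids=subject_ids,
        allele_names=hla_cols,
        copy_matrix=copy_matrix,
        responses=responses,
    )


def write_cohort_csv(cohort: CohortTable, path, include_ids: bool = True) -> None:
    """Write a cohort in the same dialect ``read_cohort_csv`` accepts.

    Peptide cells are TRUE/FALSE with blanks for missing, so a
    read -> write -> read round trip reproduces the table.
    """
    frame = pd.DataFrame()
    if include_ids:
        frame["subject"] = cohort.subject_ids
    for j, allele in enumerate(cohort.allele_names):
        frame[allele] = cohort.copy_matrix[:, j]
    for pep in cohort.peptides:
        col = cohort.responses[pep]
        frame[pep] = [
            "" if pd.isna(v) else ("TRUE" if v else "FALSE") for v in col
        ]
    frame.to_csv(path, index=False)


def write_manifest(path, config, prior_kind: str, extra: dict | None = None) -> None:
    """Reproducibility manifest: seed, chain settings, prior provenance."""
    payload = {
        "chain_length": config.chain_length,
        "burn_in_fraction": config.burn_in_fraction,
        "proposal_step": config.proposal_step,
        "seed": config.seed,
        "density_bins": config.density_bins,
        "prior": prior_kind,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
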