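"""Input containers and TSV/GMT parsing.

A :class:`Cohort` couples a log2-scale expression matrix (genes x samples)
with a clinical table carrying right-censored overall survival, optional
recurrence-free survival, optional RECIST chemotherapy response and free
covariate columns.  Expression is assumed to arrive already normalized and
log2 transformed; the loader validates finiteness and identifier uniqueness
but never re-normalizes.  Gene identifiers are opaque strings: no
symbol-alias mapping or probe collapsing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")

CLINICAL_REQUIRED = ("sample_id", "os_time", "os_event")
CLINICAL_OPTIONAL = ("rfs_time", "rfs_event", "chemo_response")


class DataValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set as parsed from one GMT line."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataValidationError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Cohort:
    """One study: aligned expression matrix and clinical table.

    ``expression`` is a genes x samples DataFrame (index = gene ids, columns
    = sample ids, log2 scale).  ``clinical`` is indexed by sample order with
    a ``sample_id`` column; expression columns and clinical ``sample_id`` are
    identical and identically ordered.
    """

    name: str
    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        validate_expression(self.expression)
        validate_clinical(self.clinical)
        exp_samples = list(self.expression.columns)
        clin_samples = list(self.clinical["sample_id"])
        if exp_samples != clin_samples:
            raise DataValidationError(
                f"cohort {self.name!r}: expression samples and clinical samples "
                "are not identical and identically ordered"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Cohort({self.name!r}, {self.expression.shape[0]} genes x "
            f"{self.expression.shape[1]} samples)"
        )


def validate_expression(expression: pd.DataFrame) -> None:
    if expression.shape[0] < 2 or expression.shape[1] < 2:
        raise DataValidationError(
            f"expression matrix must have at least 2 genes and 2 samples, "
            f"got {expression.shape[0]} x {expression.shape[1]}"
        )
    if expression.index.duplicated().any():
        dupes = expression.index[expression.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate gene id(s): {dupes}")
    if expression.columns.duplicated().any():
        dupes = expression.columns[expression.columns.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate sample id(s): {dupes}")
    values = expression.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataValidationError(
            f"non-finite expression value for gene {expression.index[i]!r} "
            f"in sample {expression.columns[j]!r}"
        )


def validate_clinical(clinical: pd.DataFrame) -> None:
    missing = [c for c in CLINICAL_REQUIRED if c not in clinical.columns]
    if missing:
        raise DataValidationError(f"clinical table missing required column(s): {missing}")
    if clinical["sample_id"].duplicated().any():
        dupes = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataValidationError(f"duplicate clinical sample id(s): {dupes}")
    os_time = pd.to_numeric(clinical["os_time"], errors="coerce")
    bad_time = clinical.loc[~(os_time > 0), "sample_id"].tolist()
    if bad_time:
        raise DataValidationError(f"os_time must be positive; offending sample(s): {bad_time}")
    os_event = clinical["os_event"]
    if not os_event.isin([0, 1]).all():
        bad = clinical.loc[~os_event.isin([0, 1]), "sample_id"].tolist()
        raise DataValidationError(f"os_event must be 0 or 1; offending sample(s): {bad}")
    if "chemo_response" in clinical.columns:
        resp = clinical["chemo_response"].dropna()
        resp = resp[resp.astype(str).str.len() > 0]
        unknown = sorted(set(resp.astype(str)) - set(RESPONSE_LEVELS))
        if unknown:
            raise DataValidationError(f"unknown chemo_response value(s): {unknown}")


def load_cohort(expression_path: str | Path, clinical_path: str | Path, cohort_name: str) -> Cohort:
    """Read one cohort from an expression TSV and a clinical TSV.

    The two files are restricted to their shared samples (dropped samples are
    logged) and the expression columns are reordered to clinical row order,
    which is the canonical sample order downstream.
    """
    expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    expression.index = expression.index.astype(str)
    expression.columns = expression.columns.astype(str)
    clinical = pd.read_csv(clinical_path, sep="\t", dtype={"sample_id": str})
    validate_clinical(clinical)

    exp_samples = set(expression.columns)
    clin_samples = set(clinical["sample_id"])
    shared = exp_samples & clin_samples
    if len(shared) < 2:
        raise DataValidationError(
            f"cohort {cohort_name!r}: fewer than 2 samples shared between "
            f"expression ({len(exp_samples)}) and clinical ({len(clin_samples)})"
        )
    for sample in sorted(exp_samples - shared):
        logger.warning("cohort %s: dropping expression sample %s (no clinical row)", cohort_name, sample)
    for sample in sorted(clin_samples - shared):
        logger.warning("cohort %s: dropping clinical sample %s (no expression column)", cohort_name, sample)

    clinical = clinical[clinical["sample_id"].isin(shared)].reset_index(drop=True)
    expression = expression.loc[:, list(clinical["sample_id"])]
    # canonicalize gene order so row permutations of the input are immaterial
    expression = expression.sort_index()
    return Cohort(name=cohort_name, expression=expression, clinical=clinical)


def write_cohort(cohort: Cohort, expression_path: str | Path, clinical_path: str | Path) -> None:
    """Write a cohort back to the two-file TSV dialect ``load_cohort`` reads."""
    expression = cohort.expression.copy()
    expression.index.name = "gene_id"
    expression.to_csv(expression_path, sep="\t")
    cohort.clinical.to_csv(clinical_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per tab-separated line.

    Within-set duplicate genes are collapsed with a warning; lines with no
    genes are skipped with a warning; duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                logger.warning("%s line %d: gene set %r has no genes, skipped", path, lineno, fields[0])
                continue
            name, description = fields[0], fields[1]
            if name in seen:
                raise DataValidationError(f"duplicate gene set name {name!r} in {path}")
            seen.add(name)
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if len(set(genes)) < len(genes):
                logger.warning(
                    "%s line %d: gene set %r lists %d duplicate gene(s), collapsed",
                    path, lineno, name, len(genes) - len(set(genes)),
                )
            sets.append(GeneSet(name=name, description=description, members=frozenset(genes)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in gene_sets:
            handle.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")
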