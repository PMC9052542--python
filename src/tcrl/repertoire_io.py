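"""Reading, validation, and alignment of repertoire, covariate, and phenotype tables.

A repertoire table is a long-format delimited file with one row per
(subject, CDR3 amino-acid sequence) pair carrying a clone abundance.
Column names are configurable so that exports from common clonotyping
pipelines (AIRR, MiXCR, TRUST4, ...) can be read by renaming columns
rather than by format-specific parsers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)


class RepertoireFormatError(ValueError):
    """Raised when an input table is structurally malformed."""


class RepertoireValidationError(ValueError):
    """Raised when a table row violates a data invariant."""


@dataclass
class Repertoire:
    """One subject's set of unique CDR3 amino-acid sequences with clone abundances.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    sequences : list of str
        Unique amino-acid sequences over the 20-letter standard alphabet.
    abundances : numpy.ndarray of int
        Clone count for each sequence, all >= 1, same length as ``sequences``.
    annotations : dict, optional
        Per-sequence annotation columns (e.g. V segment, nucleotide
        sequence) carried through as opaque string lists.
    """

    subject_id: str
    sequences: list[str]
    abundances: np.ndarray
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=np.int64)
        if len(self.sequences) != len(self.abundances):
            raise RepertoireValidationError(
                f"subject {self.subject_id!r}: {len(self.sequences)} sequences "
                f"but {len(self.abundances)} abundances"
            )
        if len(self.sequences) == 0:
            raise RepertoireValidationError(
                f"subject {self.subject_id!r}: empty repertoire"
            )
        if len(set(self.sequences)) != len(self.sequences):
            raise RepertoireValidationError(
                f"subject {self.subject_id!r}: duplicate sequences"
            )
        if np.any(self.abundances < 1):
            raise RepertoireValidationError(
                f"subject {self.subject_id!r}: abundances must be >= 1"
            )
        for seq in self.sequences:
            validate_sequence(seq, context=f"subject {self.subject_id!r}")

    @property
    def m(self) -> int:
        """Number of unique sequences in this repertoire."""
        return len(self.sequences)

    @property
    def total_abundance(self) -> int:
        """Total clone count, i.e. the sum of abundances."""
        return int(self.abundances.sum())


@dataclass
class RepertoireSet:
    """An ordered cohort of repertoires, one per subject."""

    repertoires: list[Repertoire]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.repertoires]
        if len(set(ids)) != len(ids):
            raise RepertoireValidationError("duplicate subject IDs in cohort")

    @property
    def n(self) -> int:
        return len(self.repertoires)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.repertoires]

    def __iter__(self):
        return iter(self.repertoires)

    def __getitem__(self, i: int) -> Repertoire:
        return self.repertoires[i]

    def __len__(self) -> int:
        return len(self.repertoires)


@dataclass
class CovariateTable:
    """Design matrix of confounders: an intercept column followed by q covariates.

    Row order matches the companion :class:`RepertoireSet`.
    """

    X: np.ndarray
    subject_ids: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise RepertoireValidationError("covariate matrix must be 2-D")
        if self.X.shape[0] != len(self.subject_ids):
            raise RepertoireValidationError("covariate rows != subject IDs")
        if not np.allclose(self.X[:, 0], 1.0):
            raise RepertoireValidationError(
                "first covariate column must be the intercept (all ones)"
            )
        if not np.all(np.isfinite(self.X)):
            raise RepertoireValidationError("covariates contain non-finite values")
        if not self.names:
            self.names = ["intercept"] + [
                f"x{j}" for j in range(1, self.X.shape[1])
            ]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        """Number of confounders (excluding the intercept)."""
        return self.X.shape[1] - 1


@dataclass
class PhenotypeVector:
    """Length-n trait vector, either binary (0/1) or continuous."""

    y: np.ndarray
    trait_type: str
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.trait_type not in ("binary", "continuous"):
            raise RepertoireValidationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        if self.y.ndim != 1 or len(self.y) != len(self.subject_ids):
            raise RepertoireValidationError("phenotype length != subject IDs")
        if not np.all(np.isfinite(self.y)):
            raise RepertoireValidationError("phenotype contains non-finite values")
        if self.trait_type == "binary":
            if not np.all(np.isin(self.y, (0.0, 1.0))):
                raise RepertoireValidationError("binary trait must take values in {0,1}")
            if len(np.unique(self.y)) < 2:
                raise RepertoireValidationError("binary trait has only one class")

    @property
    def n(self) -> int:
        return len(self.y)


def validate_sequence(seq: str, context: str = "") -> None:
    """Check that ``seq`` is non-empty and uses only standard one-letter codes."""
    prefix = f"{context}: " if context else ""
    if not isinstance(seq, str) or len(seq) == 0:
        raise RepertoireValidationError(f"{prefix}empty amino-acid sequence")
    bad = set(seq) - _AA_SET
    if bad:
        raise RepertoireValidationError(
            f"{prefix}sequence {seq!r} contains non-standard letters {sorted(bad)}"
        )


def read_repertoire_table(
    path,
    *,
    sep: str = "\t",
    col_subject: str = "subject_id",
    col_seq: str = "amino_acid",
    col_count: str = "abundance",
    annotation_cols: list[str] | None = None,
) -> RepertoireSet:
    """Read a long-format repertoire table into a :class:`RepertoireSet`.

    Rows are grouped by subject in first-appearance order. Duplicate
    (subject, sequence) rows have their abundances summed. Sequences are
    validated strictly against the 20-letter alphabet: an invalid row
    raises rather than being silently dropped, so the cohort composition
    is reproducible.

    Parameters
    ----------
    path : path-like or buffer
        Delimited text file with a header row.
    sep : str
        Field delimiter, tab by default.
    col_subject, col_seq, col_count : str
        Names of the subject-ID, amino-acid-sequence, and abundance
        columns in the file.
    annotation_cols : list of str, optional
        Extra columns to carry through as per-sequence annotations.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise RepertoireFormatError(f"empty repertoire table: {path}") from None
    missing = [c for c in (col_subject, col_seq, col_count) if c not in df.columns]
    if missing:
        raise RepertoireFormatError(
            f"repertoire table missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise RepertoireFormatError(f"repertoire table has a header but no rows: {path}")
    annotation_cols = annotation_cols or []
    for c in annotation_cols:
        if c not in df.columns:
            raise RepertoireFormatError(f"annotation column {c!r} not in table")

    counts = pd.to_numeric(df[col_count], errors="coerce")
    bad_rows = counts.isna() | (counts <= 0) | (counts != counts.round())
    if bad_rows.any():
        row = int(np.flatnonzero(bad_rows.to_numpy())[0])
        raise RepertoireValidationError(
            f"row {row + 2} of {path}: abundance {df[col_count].iloc[row]!r} "
            "is not a positive integer"
        )
    df = df.assign(**{col_count: counts.astype(np.int64)})

    for row_idx, seq in enumerate(df[col_seq]):
        try:
            validate_sequence(seq)
        except RepertoireValidationError as exc:
            raise RepertoireValidationError(f"row {row_idx + 2} of {path}: {exc}") from None

    repertoires: list[Repertoire] = []
    # groupby(sort=False) preserves first-appearance subject order
    for sid, grp in df.groupby(col_subject, sort=False):
        merged = grp.groupby(col_seq, sort=False)[col_count].sum()
        ann: dict[str, list[str]] = {}
        for c in annotation_cols:
            first = grp.drop_duplicates(subset=col_seq, keep="first").set_index(col_seq)[c]
            ann[c] = [str(first.loc[s]) for s in merged.index]
        repertoires.append(
            Repertoire(
                subject_id=str(sid),
                sequences=list(merged.index),
                abundances=merged.to_numpy(),
                annotations=ann,
            )
        )
    return RepertoireSet(repertoires)


def write_repertoire_table(
    rs: RepertoireSet,
    path,
    *,
    sep: str = "\t",
    col_subject: str = "subject_id",
    col_seq: str = "amino_acid",
    col_count: str = "abundance",
) -> None:
    """Write a :class:`RepertoireSet` back to a long-format delimited table."""
    rows = []
    for rep in rs:
        for seq, w in zip(rep.sequences, rep.abundances):
            rows.append({col_subject: rep.subject_id, col_seq: seq, col_count: int(w)})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def filter_min_unique(rs: RepertoireSet, min_unique: int = 2) -> RepertoireSet:
    """Drop subjects with fewer than ``min_unique`` unique sequences.

    The default of 2 excludes single-sequence repertoires, for which the
    homology kernel and diversity measures carry no information.
    """
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    kept = [r for r in rs if r.m >= min_unique]
    dropped = [r.subject_id for r in rs if r.m < min_unique]
    if dropped:
        logger.info(
            "filter_min_unique: excluded %d subject(s) with < %d unique sequences: %s",
            len(dropped), min_unique, dropped,
        )
    if not kept:
        raise RepertoireValidationError(
            f"no subjects remain after requiring >= {min_unique} unique sequences"
        )
    return RepertoireSet(kept)


def read_covariate_table(
    path, *, sep: str = "\t", col_subject: str = "subject_id",
) -> CovariateTable:
    """Read a covariate table (subject-ID column + numeric confounders).

    An intercept column of ones is prepended; it must not be present in
    the file.
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise RepertoireFormatError(f"empty covariate table: {path}") from None
    if col_subject not in df.columns:
        raise RepertoireFormatError(f"covariate table missing column {col_subject!r}")
    ids = [str(s) for s in df[col_subject]]
    conf = df.drop(columns=[col_subject]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), conf])
    names = ["intercept"] + [c for c in df.columns if c != col_subject]
    return CovariateTable(X=X, subject_ids=ids, names=names)


def read_phenotype_table(
    path,
    trait_type: str,
    *,
    sep: str = "\t",
    col_subject: str = "subject_id",
    col_value: str = "phenotype",
) -> PhenotypeVector:
    """Read a phenotype table (subject-ID column + one trait column)."""
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise RepertoireFormatError(f"empty phenotype table: {path}") from None
    for c in (col_subject, col_value):
        if c not in df.columns:
            raise RepertoireFormatError(f"phenotype table missing column {c!r}")
    return PhenotypeVector(
        y=df[col_value].to_numpy(dtype=float),
        trait_type=trait_type,
        subject_ids=[str(s) for s in df[col_subject]],
    )


def align_tables(
    rs: RepertoireSet, cov: CovariateTable, phe: PhenotypeVector,
) -> tuple[RepertoireSet, CovariateTable, PhenotypeVector]:
    """Inner-join repertoires, covariates, and phenotype on subject ID.

    The result is ordered by the repertoire set's subject order; subjects
    missing from any of the three tables are dropped with a logged count.
    """
    cov_idx = {sid: i for i, sid in enumerate(cov.subject_ids)}
    phe_idx = {sid: i for i, sid in enumerate(phe.subject_ids)}
    kept = [r for r in rs if r.subject_id in cov_idx and r.subject_id in phe_idx]
    n_dropped = rs.n - len(kept)
    if n_dropped:
        logger.info("align_tables: dropped %d subject(s) missing from a table", n_dropped)
    if not kept:
        raise RepertoireValidationError(
            "no subjects shared between repertoires, covariates, and phenotype"
        )
    ids = [r.subject_id for r in kept]
    X = cov.X[[cov_idx[s] for s in ids]]
    y = phe.y[[phe_idx[s] for s in ids]]
    return (
        RepertoireSet(kept),
        CovariateTable(X=X, subject_ids=ids, names=list(cov.names)),
        PhenotypeVector(y=y, trait_type=phe.trait_type, subject_ids=ids),
    )
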