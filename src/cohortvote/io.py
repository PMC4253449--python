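"""Tabular I/O for expression cohorts, annotations and signature tables.

All files are plain TSV, UTF-8, '.' decimal separator.  Expression matrices
have a header row of sample ids and a first column of probe/gene ids; values
are stored on linear scale internally, with an auto-detection rule for files
saved on the log2 scale.  Probe-level matrices are collapsed to gene symbols
by keeping, per symbol, the probe with the greatest median intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCohort",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotation",
    "assemble_cohort",
    "collapse_probes",
    "SIGNATURE_COLUMNS",
    "write_signature",
    "read_signature",
]

GROUP_LABELS = ("primary", "secondary")

#: Matrix maxima below this are taken to be log2 intensities under
#: ``scale_hint="auto"``: log2 microarray values rarely exceed ~16 while
#: linear intensities rarely peak below ~30.
LOG2_AUTO_THRESHOLD = 30.0


class ParseError(ValueError):
    """A malformed input file (carries a line number where applicable)."""


@dataclass
class ExpressionCohort:
    """One cohort: a gene x sample linear-scale matrix plus group labels.

    ``values`` rows are unique gene (or probe) identifiers, columns unique
    sample ids; ``group`` maps every sample to ``primary`` or ``secondary``.
    """

    cohort_id: str
    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.cohort_id}: duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.cohort_id}: duplicate sample identifiers")
        if not self.group.index.equals(self.values.columns):
            self.group = self.group.reindex(self.values.columns)
        bad = set(self.group.dropna().unique()) - set(GROUP_LABELS)
        if bad or self.group.isna().any():
            raise ValueError(
                f"{self.cohort_id}: group labels must be one of {GROUP_LABELS}"
            )
        for label in GROUP_LABELS:
            if (self.group == label).sum() < 1:
                raise ValueError(
                    f"{self.cohort_id}: no samples labeled '{label}'"
                )
        # zeros are tolerated (handled by the pseudocount rule downstream);
        # negative intensities are always a preprocessing error
        if (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.cohort_id}: negative expression values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, label: str) -> pd.Index:
        return self.group.index[self.group == label]


def read_expression_matrix(
    path: str | Path, scale_hint: str = "auto"
) -> pd.DataFrame:
    """Read a TSV expression matrix, returning values on LINEAR scale.

    ``scale_hint`` is one of ``auto``, ``log2``, ``linear``.  Under ``auto``
    the matrix is treated as log2 (and exponentiated) when its maximum is
    below 30; the decision is logged.  Rows containing missing values are
    dropped with a logged count.  Duplicate sample ids, ragged rows and
    non-numeric cells raise :class:`ParseError` with a 1-based line number.
    """
    if scale_hint not in ("auto", "log2", "linear"):
        raise ValueError("scale_hint must be one of auto, log2, linear")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}, line 1: duplicate sample ids {dupes}")
    n_fields = len(header)

    ids: list[str] = []
    rows: list[list[float]] = []
    n_dropped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}, line {lineno}: expected {n_fields} fields, "
                f"got {len(fields)}"
            )
        cells = fields[1:]
        if any(c.strip() in ("", "NA", "NaN", "nan", "null") for c in cells):
            n_dropped += 1
            continue
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: non-numeric cell ({exc})")
        ids.append(fields[0])
    if n_dropped:
        logger.warning(
            "%s: dropped %d rows with missing values", path.name, n_dropped
        )
    matrix = pd.DataFrame(
        np.asarray(rows, dtype=float), index=pd.Index(ids, name="id"),
        columns=samples,
    )
    if matrix.index.has_duplicates:
        raise ParseError(f"{path}: duplicate row identifiers")

    if scale_hint == "log2":
        matrix = np.exp2(matrix)
    elif scale_hint == "auto":
        if matrix.size and matrix.to_numpy().max() < LOG2_AUTO_THRESHOLD:
            logger.info(
                "%s: matrix maximum %.3g < %g, treating values as log2 "
                "and exponentiating",
                path.name, matrix.to_numpy().max(), LOG2_AUTO_THRESHOLD,
            )
            matrix = np.exp2(matrix)
        else:
            logger.info("%s: treating values as linear scale", path.name)
    return matrix


def write_expression_matrix(path: str | Path, values: pd.DataFrame) -> None:
    """Write a linear-scale expression matrix in the TSV dialect."""
    values.to_csv(path, sep="\t", index_label="id", float_format="%.6g",
                  lineterminator="\n")


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read a per-sample annotation TSV.

    Requires columns ``sample_id`` and ``group`` (``primary``/``secondary``);
    optional ``time``, ``event``, ``grade``, ``stage``.  Returns a DataFrame
    indexed by sample id.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in ann.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    if ann["sample_id"].duplicated().any():
        dupes = sorted(ann.loc[ann["sample_id"].duplicated(), "sample_id"])
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    bad = sorted(set(ann["group"]) - set(GROUP_LABELS))
    if bad:
        raise ParseError(
            f"{path}: unknown group value(s) {bad}; allowed values are "
            f"{list(GROUP_LABELS)}"
        )
    if "event" in ann.columns:
        if not ann["event"].isin((0, 1)).all():
            raise ParseError(f"{path}: event column must be 0/1")
    return ann.set_index("sample_id")


def assemble_cohort(
    cohort_id: str, values: pd.DataFrame, annotation: pd.DataFrame
) -> ExpressionCohort:
    """Join a linear-scale matrix with its sample annotation.

    Annotated samples absent from the matrix are an error (ids listed);
    matrix samples absent from the annotation are dropped with a warning.
    """
    matrix_samples = set(values.columns)
    extra = sorted(set(annotation.index) - matrix_samples)
    if extra:
        raise ValueError(
            f"{cohort_id}: annotated samples absent from matrix: {extra}"
        )
    missing = [s for s in values.columns if s not in annotation.index]
    if missing:
        logger.warning(
            "%s: dropping %d unannotated sample(s): %s",
            cohort_id, len(missing), missing,
        )
        values = values.drop(columns=missing)
    group = annotation["group"].reindex(values.columns)
    return ExpressionCohort(cohort_id=cohort_id, values=values, group=group)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV probe_id -> gene symbol map (header required)."""
    table = pd.read_csv(path, sep="\t", dtype=str).dropna()
    probe_col, symbol_col = table.columns[:2]
    return dict(zip(table[probe_col], table[symbol_col]))


def collapse_probes(
    values: pd.DataFrame,
    probe_map: Mapping[str, str],
    method: str = "max_median",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene symbols.

    For each symbol the representative row is the mapped probe with the
    greatest median intensity across all samples (ties broken by probe id
    ascending).  Unmapped probes are dropped; symbols are upper-cased so
    cross-platform matching is case-insensitive.
    """
    if method != "max_median":
        raise ValueError(f"unknown collapse method '{method}'")
    mapped = {
        probe: str(sym).strip().upper()
        for probe, sym in probe_map.items()
        if probe in values.index and str(sym).strip()
    }
    if not mapped:
        raise ValueError("no probe in the map matches a matrix row")
    sub = values.loc[list(mapped)]
    medians = sub.median(axis=1)
    choice = pd.DataFrame(
        {"symbol": [mapped[p] for p in sub.index], "median": medians.to_numpy()},
        index=sub.index,
    )
    # max-median probe per symbol; probe-id ascending breaks exact ties
    choice = choice.sort_values(
        ["symbol", "median"], ascending=[True, False], kind="mergesort"
    )
    winners = choice[~choice["symbol"].duplicated()]
    out = values.loc[winners.index].copy()
    out.index = pd.Index(winners["symbol"].to_numpy(), name="id")
    return out.sort_index()


SIGNATURE_COLUMNS = [
    "gene",
    "duplication_times",
    "cohorts_measured",
    "median_fold_change",
    "p_binom",
    "q_bh",
    "rank",
]


def write_signature(path: str | Path, signature: pd.DataFrame) -> None:
    """Write an integrated signature as TSV (schema in SIGNATURE_COLUMNS).

    ``p_binom``/``q_bh`` may be empty before calibration; NaN in any other
    column is an error.  Output is byte-stable across runs (fixed 6-significant
    -digit float formatting).
    """
    sig = signature.reset_index() if signature.index.name == "gene" else signature
    missing = [c for c in SIGNATURE_COLUMNS if c not in sig.columns]
    if missing:
        raise ValueError(f"signature missing columns {missing}")
    sig = sig[SIGNATURE_COLUMNS]
    core = sig[["gene", "duplication_times", "cohorts_measured",
                "median_fold_change", "rank"]]
    if core.isna().any().any():
        bad = core.columns[core.isna().any()].tolist()
        raise ValueError(f"NaN in required signature column(s) {bad}")
    sig.to_csv(path, sep="\t", index=False, float_format="%.6g",
               lineterminator="\n")


def read_signature(path: str | Path) -> pd.DataFrame:
    """Read a signature TSV written by :func:`write_signature`."""
    sig = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in SIGNATURE_COLUMNS if c not in sig.columns]
    if missing:
        raise ParseError(f"{path}: missing signature column(s) {missing}")
    for col in ("duplication_times", "cohorts_measured", "rank"):
        sig[col] = sig[col].astype(int)
    return sig
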