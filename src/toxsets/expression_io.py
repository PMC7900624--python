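"""Read and validate gene-level fold-change tables.

The input is the user's differential-expression result: one row per
gene with a gene identifier, a log-transformed fold-change value, and
an optional gene-level p-value. Tab- and comma-separated files are
auto-detected, a single header line is tolerated, and duplicate gene
identifiers are collapsed (mean log FC, minimum p).

Values are log fold changes by default; the same column also accepts
other signed per-gene effect measures (e.g. Kallisto/sleuth beta values
or z-scores). Linear fold changes can be read with ``scale="linear"``,
which applies log2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable

from toxsets.errors import DomainError, FormatError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene: identifier, finite log fold change, optional p in (0, 1]."""

    gene_id: str
    log_fc: float
    gene_p: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_fc):
            raise DomainError(f"gene {self.gene_id!r}: log FC must be finite")
        if self.gene_p is not None and not (0.0 < self.gene_p <= 1.0):
            raise DomainError(
                f"gene {self.gene_id!r}: p-value {self.gene_p} outside (0, 1]"
            )


@dataclass(frozen=True)
class ExpressionTable:
    """Per-gene records keyed by unique gene identifier.

    ``n_input_rows`` counts data rows read; ``n_duplicates_collapsed``
    counts rows merged into an earlier gene's record.
    """

    records: dict[str, ExpressionRecord]
    namespace: str = "other"
    n_input_rows: int = 0
    n_duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        if self.n_input_rows < len(self.records):
            raise ValueError("n_input_rows smaller than number of records")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records


def _parse_float(token: str, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise FormatError(
            f"line {lineno}: non-numeric {what} field {token!r}"
        ) from None
    if not math.isfinite(value):
        raise DomainError(f"line {lineno}: {what} {token!r} is not finite")
    return value


def _detect_delimiter(line: str, lineno: int) -> str:
    has_tab = "\t" in line
    has_comma = "," in line
    if has_tab:
        # Tab wins; commas inside tab-separated fields are data.
        return "\t"
    if has_comma:
        return ","
    raise FormatError(
        f"line {lineno}: could not detect delimiter (no tab or comma)"
    )


def read_expression_table(
    stream: IO[str] | Iterable[str],
    scale: str = "log",
    namespace: str = "other",
) -> ExpressionTable:
    """Parse a 2- or 3-column fold-change table.

    Parameters
    ----------
    stream : readable text
        Lines of ``gene_id<sep>value[<sep>p_value]`` where ``<sep>`` is a
        tab or comma, auto-detected from the first data line. A single
        header line is detected by a non-numeric second field and skipped.
    scale : {"log", "linear"}
        With ``"log"`` (default) values pass through unchanged; with
        ``"linear"`` values must be positive and are transformed to log2.
    namespace : str
        Identifier namespace tag recorded on the table.

    Raises
    ------
    FormatError
        Non-numeric fold-change field, wrong column count, ambiguous
        delimiter — all with the offending line number.
    DomainError
        Linear value <= 0, or a p-value outside (0, 1].
    InputError
        No data rows at all.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"scale must be 'log' or 'linear', got {scale!r}")

    delimiter: str | None = None
    header_skipped = False
    # Per gene: list of (log_fc, gene_p) pending collapse.
    pending: dict[str, list[tuple[float, float | None]]] = {}
    n_rows = 0

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if delimiter is None:
            delimiter = _detect_delimiter(line, lineno)
        fields = [f.strip() for f in line.split(delimiter)]
        while fields and fields[-1] == "":
            fields.pop()
        if len(fields) < 2 or len(fields) > 3:
            raise FormatError(
                f"line {lineno}: expected 2 or 3 {'tab' if delimiter == chr(9) else 'comma'}-"
                f"separated columns, got {len(fields)}"
            )
        if not header_skipped and n_rows == 0:
            # Header heuristic: second field is not a number.
            try:
                float(fields[1])
            except ValueError:
                header_skipped = True
                continue
        gene_id, value_token = fields[0], fields[1]
        value = _parse_float(value_token, lineno, "fold-change")
        if scale == "linear":
            if value <= 0:
                raise DomainError(
                    f"line {lineno}: linear fold change must be > 0, got {value}"
                )
            log_fc = math.log2(value)
        else:
            log_fc = value
        gene_p: float | None = None
        if len(fields) == 3 and fields[2] != "":
            gene_p = _parse_float(fields[2], lineno, "p-value")
            if not (0.0 < gene_p <= 1.0):
                raise DomainError(
                    f"line {lineno}: p-value {gene_p} outside (0, 1]"
                )
        n_rows += 1
        pending.setdefault(gene_id, []).append((log_fc, gene_p))

    if n_rows == 0:
        raise InputError("expression table contains no data rows")

    records: dict[str, ExpressionRecord] = {}
    n_collapsed = 0
    for gene_id, values in pending.items():
        n_collapsed += len(values) - 1
        log_fc = sum(v for v, _ in values) / len(values)
        ps = [p for _, p in values if p is not None]
        gene_p = min(ps) if ps else None
        records[gene_id] = ExpressionRecord(gene_id, log_fc, gene_p)
    if n_collapsed:
        logger.warning(
            "collapsed %d duplicate gene row(s): mean log FC, min p-value",
            n_collapsed,
        )
    return ExpressionTable(
        records=records,
        namespace=namespace,
        n_input_rows=n_rows,
        n_duplicates_collapsed=n_collapsed,
    )


def background_values(table: ExpressionTable) -> list[float]:
    """All log FC values in gene-id-sorted order (the resampling universe).

    The deterministic order makes seeded downstream resampling independent
    of input file ordering.
    """
    if len(table) == 0:
        raise InputError("expression table is empty")
    return [table.records[g].log_fc for g in sorted(table.records)]
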