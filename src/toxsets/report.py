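"""Rank activation results, serialize them, and drill down to genes.

The default presentation ranks gene sets by the AAFC z-score, the
direction-agnostic disruption signal. Sets whose AAFC z is not positive
(less disrupted than a random set) are floored below all positively
scoring sets; unscored and degenerate sets sink to the bottom. Ties are
broken by set name so the ordering is total and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO

from statsmodels.stats.multitest import multipletests

from toxsets.engine import ActivationResult
from toxsets.errors import DomainError, InputError
from toxsets.expression_io import ExpressionTable
from toxsets.geneset_io import GeneSet

RANK_KEYS = ("aafc_z", "afc_z", "fisher_p")

#: TSV column order; z-scores print with 4 decimals, p-values in
#: scientific notation, missing values as "NA".
TSV_COLUMNS = (
    "set_name",
    "n_set",
    "n_matched",
    "afc_z",
    "afc_p",
    "direction",
    "aafc_z",
    "aafc_p",
    "aafc_significant",
    "fisher_p",
    "fisher_k",
    "flags",
)
ADJUSTED_COLUMNS = ("afc_p_adj", "aafc_p_adj", "fisher_p_adj")


@dataclass(frozen=True)
class RankedReport:
    """Ordered activation results plus the key and adjustment used."""

    rows: tuple[ActivationResult, ...]
    rank_key: str
    adjusted: bool = False


@dataclass(frozen=True)
class GeneContribution:
    """One matched gene's contribution to a set's score."""

    gene_id: str
    log_fc: float
    abs_log_fc: float
    gene_p: float | None = None


def _sort_group(result: ActivationResult, key: str) -> int:
    """Rank stratum: confident results first, flagged results last."""
    if result.unscored:
        return 3
    if result.degenerate:
        return 2
    if key == "aafc_z" and not result.aafc_significant:
        return 1  # floor non-positive AAFC z below all activated sets
    if key == "fisher_p" and result.fisher_p is None:
        return 1  # sets without gene-level p-values cannot rank by Fisher
    return 0


def rank_results(
    results: list[ActivationResult],
    key: str = "aafc_z",
    adjusted: bool = False,
) -> RankedReport:
    """Order results by a rank key into a :class:`RankedReport`.

    z keys sort descending, ``fisher_p`` ascending; unscored/degenerate
    rows follow all scored rows and ties break by set name. With
    ``adjusted=True``, Benjamini-Hochberg adjusted p-values are computed
    across the scored sets and attached as extra columns — the ordering
    itself never changes.
    """
    if key not in RANK_KEYS:
        raise DomainError(
            f"unknown rank key {key!r}; expected one of {RANK_KEYS}"
        )
    if not results:
        raise InputError("no results to rank")

    if adjusted:
        results = [ActivationResult(**vars(r)) for r in results]
        for attr, adj_attr in (
            ("afc_p", "afc_p_adj"),
            ("aafc_p", "aafc_p_adj"),
            ("fisher_p", "fisher_p_adj"),
        ):
            scored = [r for r in results if getattr(r, attr) is not None]
            if scored:
                _, p_adj, _, _ = multipletests(
                    [getattr(r, attr) for r in scored], method="fdr_bh"
                )
                for r, p in zip(scored, p_adj):
                    setattr(r, adj_attr, float(p))

    def sort_key(r: ActivationResult):
        group = _sort_group(r, key)
        value = getattr(r, key)
        if value is None or group >= 2:
            metric = 0.0
        elif key == "fisher_p":
            metric = value  # ascending: small p first
        else:
            metric = -value  # descending: large z first
        return (group, metric, r.set_name)

    return RankedReport(
        rows=tuple(sorted(results, key=sort_key)),
        rank_key=key,
        adjusted=adjusted,
    )


def contributing_genes(
    gene_set: GeneSet, table: ExpressionTable
) -> list[GeneContribution]:
    """Matched genes of a set, largest |log FC| first (ties by gene id).

    This is the per-set drill-down: the genes driving the AFC/AAFC
    signal appear at the top. The listed log FC values sum exactly to
    the set's AFC score.
    """
    rows = [
        GeneContribution(
            gene_id=g,
            log_fc=table.records[g].log_fc,
            abs_log_fc=abs(table.records[g].log_fc),
            gene_p=table.records[g].gene_p,
        )
        for g in gene_set.members
        if g in table.records
    ]
    rows.sort(key=lambda c: (-c.abs_log_fc, c.gene_id))
    return rows


def _fmt(value, column: str) -> str:
    if value is None:
        return "NA"
    if column == "flags":
        return ",".join(value) if value else "-"
    if column in ("aafc_significant",):
        return "true" if value else "false"
    if column.endswith("_z"):
        return f"{value:.4f}"
    if column.endswith("_p") or column.endswith("_p_adj"):
        return f"{value:.4e}"
    return str(value)


def write_results(report: RankedReport, stream: IO[str], format: str = "tsv") -> None:
    """Serialize a ranked report as TSV (human) or JSON (lossless).

    TSV renders z-scores with 4 decimals and p-values in scientific
    notation; JSON mirrors every result field at full precision and
    round-trips exactly.
    """
    if format == "tsv":
        columns = TSV_COLUMNS + (ADJUSTED_COLUMNS if report.adjusted else ())
        stream.write("\t".join(columns) + "\n")
        for row in report.rows:
            stream.write(
                "\t".join(_fmt(getattr(row, c), c) for c in columns) + "\n"
            )
    elif format == "json":
        payload = {
            "rank_key": report.rank_key,
            "adjusted": report.adjusted,
            "results": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(r).items()}
                for r in report.rows
            ],
        }
        json.dump(payload, stream, indent=2)
        stream.write("\n")
    else:
        raise DomainError(f"unknown output format {format!r}")


def read_results_json(stream: IO[str]) -> RankedReport:
    """Inverse of :func:`write_results` for the JSON format."""
    payload = json.load(stream)
    rows = []
    for entry in payload["results"]:
        entry = dict(entry)
        entry["flags"] = tuple(entry.get("flags", ()))
        rows.append(ActivationResult(**entry))
    return RankedReport(
        rows=tuple(rows),
        rank_key=payload["rank_key"],
        adjusted=payload["adjusted"],
    )
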