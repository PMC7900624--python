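"""Synthetic expression tables and gene-set collections with planted signal.

The generator emulates the statistical structure the scoring methods
assume: a background of null log fold changes (independent Normal(0,
noise_sd) per gene, the simplest symmetric null) on top of which chosen
gene sets are coherently perturbed. Two perturbation modes map onto the
two statistics:

* ``shift`` adds a constant effect to every planted gene — detectable
  by both AFC (signed) and AAFC;
* ``mixed-sign`` adds the effect magnitude with a sign-balanced random
  assignment (half the genes up, half down) — the set is strongly
  disrupted (AAFC) while its net fold change stays near zero (AFC-null).

Optional gene-level p-values are the two-sided normal tail probability
of log_fc / noise_sd, so they are uniform under the null and small for
planted genes.

Placeholder injury-module memberships at the declared manifest sizes
are available for pipeline tests; they are synthetic stand-ins, not the
curated module gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from toxsets.errors import DomainError
from toxsets.expression_io import ExpressionRecord, ExpressionTable
from toxsets.geneset_io import (
    GeneSet,
    GeneSetCollection,
    load_injury_manifest,
    unique_module_name,
)

MODES = ("shift", "mixed-sign")


@dataclass(frozen=True)
class PlantedSet:
    """One spiked gene set: name, size, effect magnitude, mode."""

    name: str
    size: int
    effect: float
    mode: str = "shift"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise DomainError("planted set size must be >= 1")
        if self.mode not in MODES:
            raise DomainError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SpikeInDesign:
    """Spike-in experiment: background size, noise level, planted sets.

    ``noise_sd`` is the standard deviation of null log2 fold changes
    (0.3 is a realistic replicate-to-replicate level for bulk
    expression data); ``with_p_values`` controls whether gene-level
    p-values are generated alongside.
    """

    n_background_genes: int = 1000
    noise_sd: float = 0.3
    planted_sets: tuple[PlantedSet, ...] = ()
    seed: int = 17
    with_p_values: bool = True

    def __post_init__(self) -> None:
        if self.n_background_genes < 1:
            raise DomainError("n_background_genes must be >= 1")
        if not self.noise_sd > 0:
            raise DomainError("noise_sd must be > 0")
        for p in self.planted_sets:
            if p.size >= self.n_background_genes:
                raise DomainError(
                    f"planted set {p.name!r} (size {p.size}) does not fit in "
                    f"a background of {self.n_background_genes} genes"
                )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def generate_background(design: SpikeInDesign) -> ExpressionTable:
    """Null expression table: gene ids G000001.., log FC ~ Normal(0, sd).

    Gene-level p-values (if enabled) are the exact two-sided tail
    probability of each standardized log FC, hence Uniform(0, 1] under
    this null.
    """
    rng = np.random.default_rng(design.seed)
    ids = _gene_ids(design.n_background_genes)
    log_fc = rng.normal(0.0, design.noise_sd, size=design.n_background_genes)
    if design.with_p_values:
        gene_p = 2.0 * stats.norm.sf(np.abs(log_fc) / design.noise_sd)
        gene_p = np.clip(gene_p, np.finfo(float).tiny, 1.0)
    else:
        gene_p = None
    records = {
        g: ExpressionRecord(
            g,
            float(log_fc[i]),
            float(gene_p[i]) if gene_p is not None else None,
        )
        for i, g in enumerate(ids)
    }
    return ExpressionTable(
        records=records,
        namespace="other",
        n_input_rows=len(records),
        n_duplicates_collapsed=0,
    )


def plant_signal(
    table: ExpressionTable, design: SpikeInDesign
) -> tuple[ExpressionTable, GeneSetCollection]:
    """Perturb disjoint random gene sets per the design.

    Each planted set receives ``effect`` added to its genes' log FC
    (shift mode) or ``±effect`` with a random sign per gene (mixed-sign
    mode). Membership is drawn without replacement and disjoint across
    sets. Returns the modified table and the true planted memberships as
    a GMT-able collection.
    """
    total = sum(p.size for p in design.planted_sets)
    if total > len(table):
        raise DomainError(
            f"planted sets need {total} distinct genes but the table has "
            f"only {len(table)}: sets would overlap"
        )
    # entropy pair keeps this stream distinct from any scalar-seeded one
    rng = np.random.default_rng([design.seed, 1])
    genes = sorted(table.records)
    chosen = rng.permutation(len(genes))[:total]

    records = dict(table.records)
    sets: list[GeneSet] = []
    offset = 0
    for planted in design.planted_sets:
        member_ids = [genes[i] for i in chosen[offset : offset + planted.size]]
        offset += planted.size
        if planted.mode == "shift":
            deltas = np.full(planted.size, planted.effect)
        else:
            # sign-balanced: half the genes up, half down, random allocation.
            # This keeps the net fold change near zero by construction, so
            # the set is genuinely AFC-null while strongly AAFC-disrupted.
            n_up = (planted.size + 1) // 2
            signs = np.array([1.0] * n_up + [-1.0] * (planted.size - n_up))
            deltas = rng.permutation(signs) * planted.effect
        for g, d in zip(member_ids, deltas):
            old = records[g]
            new_fc = old.log_fc + float(d)
            # keep gene_p consistent with the perturbed value
            if old.gene_p is not None:
                new_p = float(
                    max(
                        2.0 * stats.norm.sf(abs(new_fc) / design.noise_sd),
                        np.finfo(float).tiny,
                    )
                )
            else:
                new_p = None
            records[g] = ExpressionRecord(g, new_fc, new_p)
        sets.append(
            GeneSet(
                name=planted.name,
                description=(
                    f"synthetic planted set: mode={planted.mode}, "
                    f"effect={planted.effect}"
                ),
                members=tuple(member_ids),
                namespace=table.namespace,
            )
        )
    new_table = ExpressionTable(
        records=records,
        namespace=table.namespace,
        n_input_rows=table.n_input_rows,
        n_duplicates_collapsed=table.n_duplicates_collapsed,
    )
    return new_table, GeneSetCollection(sets=tuple(sets), source="planted")


def decoy_collection(
    table: ExpressionTable,
    n_sets: int,
    set_size: int,
    seed: int,
    prefix: str = "DECOY",
) -> GeneSetCollection:
    """Random gene sets from the table (may overlap) — null competitors."""
    rng = np.random.default_rng(seed)
    genes = sorted(table.records)
    if set_size > len(genes):
        raise DomainError("decoy set size exceeds table size")
    sets = tuple(
        GeneSet(
            name=f"{prefix}{i + 1:03d}",
            description="synthetic random set",
            members=tuple(
                genes[j] for j in rng.permutation(len(genes))[:set_size]
            ),
            namespace=table.namespace,
        )
        for i in range(n_sets)
    )
    return GeneSetCollection(sets=sets, source="decoys")


def placeholder_injury_modules(
    seed: int, table: ExpressionTable
) -> GeneSetCollection:
    """Synthetic stand-in memberships for the 19 injury modules.

    Builds one gene set per manifest module at exactly its declared size,
    with members drawn from the table — disjoint across modules whenever
    the table is large enough (>= 837 genes, the summed declared sizes),
    otherwise drawn independently per module. These are placeholders for
    testing the pipeline shape; real module memberships are supplied by
    the user as a GMT file.
    """
    manifest = load_injury_manifest()
    largest = max(m.declared_size for m in manifest)
    if len(table) < largest:
        raise DomainError(
            f"table has {len(table)} genes; largest module needs {largest}"
        )
    rng = np.random.default_rng(seed)
    genes = sorted(table.records)
    total = sum(m.declared_size for m in manifest)
    sets: list[GeneSet] = []
    if len(genes) >= total:
        order = rng.permutation(len(genes))
        offset = 0
        for module in manifest:
            members = tuple(
                genes[i] for i in order[offset : offset + module.declared_size]
            )
            offset += module.declared_size
            sets.append(_module_set(module, members, table.namespace))
    else:
        for module in manifest:
            members = tuple(
                genes[i]
                for i in rng.permutation(len(genes))[: module.declared_size]
            )
            sets.append(_module_set(module, members, table.namespace))
    return GeneSetCollection(sets=tuple(sets), source="bundled")


def _module_set(module, members: tuple[str, ...], namespace: str) -> GeneSet:
    return GeneSet(
        name=unique_module_name(module),
        description=(
            f"synthetic placeholder membership for the {module.organ} "
            f"{module.injury_class} module ({module.declared_size} genes)"
        ),
        members=members,
        namespace=namespace,
    )
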