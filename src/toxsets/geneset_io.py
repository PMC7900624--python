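"""GMT gene-set collections and the bundled injury-module manifest.

Gene sets are named lists of opaque, case-sensitive gene identifiers.
Collections are read and written in the tab-separated GMT (Gene Matrix
Transposed) format used by MSigDB: one set per line, fields are
``name<TAB>description<TAB>gene1<TAB>gene2...``.

The bundled manifest describes the 19 liver/kidney injury modules —
gene sets each associated with one graded histopathological injury
phenotype in rats (derived from the TG-GATEs chemical-exposure
database). Only metadata is bundled (organ, injury class, name,
declared gene count); the member gene lists belong to the prior study
that derived the modules and are supplied by the user as a GMT file,
or fabricated at declared sizes by :mod:`toxsets.fixtures` for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable

from toxsets.errors import FormatError

logger = logging.getLogger(__name__)

#: Recognised gene-identifier namespaces. The bundled injury modules are
#: keyed by rat Entrez IDs; "other" identifiers require a custom GMT.
NAMESPACES = ("human-entrez", "rat-entrez", "other")


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered set of unique gene identifiers.

    Parameters
    ----------
    name : str
        Non-empty label, unique within a collection.
    description : str
        Free text; may be empty.
    members : tuple of str
        Unique gene identifiers in source order.
    namespace : str
        One of :data:`NAMESPACES`.
    """

    name: str
    description: str
    members: tuple[str, ...]
    namespace: str = "other"

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set name must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.name!r} has duplicate members")
        if self.namespace not in NAMESPACES:
            raise FormatError(f"unknown namespace {self.namespace!r}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    """A list of gene sets with unique names plus provenance text."""

    sets: tuple[GeneSet, ...]
    source: str = "unknown"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise FormatError(f"duplicate gene set name {dup!r} in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterable[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)


@dataclass(frozen=True)
class ModuleDescriptor:
    """One injury-module manifest row: organ, injury class, name, size."""

    organ: str
    injury_class: str
    name: str
    declared_size: int

    def __post_init__(self) -> None:
        if self.organ not in ("liver", "kidney"):
            raise ValueError(f"organ must be liver or kidney, got {self.organ!r}")
        if self.injury_class not in ("inflammation", "degeneration", "proliferation"):
            raise ValueError(f"unknown injury class {self.injury_class!r}")
        if self.declared_size <= 0:
            raise ValueError("declared_size must be positive")


# The 19 injury modules: (organ, injury class, module name, gene count).
# 11 liver + 8 kidney, grouped into inflammation / degeneration /
# proliferation. Module names that occur in both organs are disambiguated
# with an organ suffix only where a unique set name is needed (GMT output);
# the manifest keeps the printed names.
_INJURY_MANIFEST: tuple[tuple[str, str, str, int], ...] = (
    ("liver", "inflammation", "Fibrogenesis", 48),
    ("liver", "inflammation", "Cellular infiltration", 25),
    ("liver", "inflammation", "Hematopoiesis", 27),
    ("liver", "inflammation", "Single cell necrosis", 11),
    ("liver", "degeneration", "Anisonucleosis", 65),
    ("liver", "degeneration", "Nuclear alteration", 111),
    ("liver", "degeneration", "Cytoplasmic alteration", 18),
    ("liver", "degeneration", "Granular degeneration", 18),
    ("liver", "proliferation", "Bile duct proliferation", 16),
    ("liver", "proliferation", "Oval cell proliferation", 126),
    ("liver", "proliferation", "Cellular foci", 35),
    ("kidney", "inflammation", "Necrosis", 18),
    ("kidney", "inflammation", "Fibrogenesis", 125),
    ("kidney", "inflammation", "Cellular infiltration", 42),
    ("kidney", "degeneration", "Degeneration", 65),
    ("kidney", "degeneration", "Dilatation", 8),
    ("kidney", "degeneration", "Inclusion bodies (cytoplasmic)", 40),
    ("kidney", "degeneration", "Casts (hyaline)", 23),
    ("kidney", "degeneration", "Hypertrophy", 16),
)


def load_injury_manifest() -> list[ModuleDescriptor]:
    """Return the 19 bundled injury-module descriptors (metadata only)."""
    return [ModuleDescriptor(*row) for row in _INJURY_MANIFEST]


def unique_module_name(descriptor: ModuleDescriptor) -> str:
    """Collection-unique name for a manifest module.

    Module names unique across organs are kept verbatim; the two names
    shared by liver and kidney get an organ qualifier.
    """
    clashes = {
        name
        for name in (r[2] for r in _INJURY_MANIFEST)
        if sum(1 for r in _INJURY_MANIFEST if r[2] == name) > 1
    }
    if descriptor.name in clashes:
        return f"{descriptor.name} ({descriptor.organ})"
    return descriptor.name


def parse_gmt(
    stream: IO[str] | Iterable[str],
    source: str = "stream",
    namespace: str = "other",
) -> GeneSetCollection:
    """Parse a GMT text stream into a :class:`GeneSetCollection`.

    Every non-empty line must have at least three tab-separated fields:
    name, description, and one or more gene identifiers. Member order is
    preserved; duplicate members within a set are collapsed with a logged
    warning. Trailing empty fields (a common exporter artifact) are
    ignored.

    Raises
    ------
    FormatError
        If a line has fewer than three fields (the message names the line
        number) or two sets share a name.
    """
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        while fields and fields[-1] == "":
            fields.pop()
        if len(fields) < 3:
            raise FormatError(
                f"{source}, line {lineno}: GMT line needs >= 3 tab-separated "
                f"fields (name, description, gene...), got {len(fields)}"
            )
        name, description, *genes = fields
        if not name:
            raise FormatError(f"{source}, line {lineno}: empty gene set name")
        if name in seen_names:
            raise FormatError(
                f"{source}, line {lineno}: duplicate gene set name {name!r}"
            )
        seen_names.add(name)
        members: list[str] = []
        member_set: set[str] = set()
        n_dup = 0
        for g in genes:
            if g in member_set:
                n_dup += 1
                continue
            member_set.add(g)
            members.append(g)
        if n_dup:
            logger.warning(
                "%s, line %d: collapsed %d duplicate member(s) in set %r",
                source,
                lineno,
                n_dup,
                name,
            )
        sets.append(
            GeneSet(
                name=name,
                description=description,
                members=tuple(members),
                namespace=namespace,
            )
        )
    return GeneSetCollection(sets=tuple(sets), source=source)


def write_gmt(collection: GeneSetCollection, stream: IO[str]) -> None:
    """Write a collection as GMT text; parse_gmt round-trips it exactly."""
    for s in collection.sets:
        stream.write("\t".join((s.name, s.description, *s.members)) + "\n")


def check_namespace(
    collection: GeneSetCollection, table_namespace: str
) -> list[str]:
    """Advisory namespace check between a collection and an input table.

    The bundled injury modules are keyed by Entrez IDs; matching them
    against a table declared as ``other`` identifiers cannot work, so a
    warning is returned (and logged). Custom collections are the user's
    responsibility and produce no warning. Never mutates anything.
    """
    if table_namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {table_namespace!r}")
    warnings: list[str] = []
    if collection.source == "bundled" and table_namespace == "other":
        msg = (
            "bundled injury modules are Entrez-keyed; matching against a "
            "table with 'other' gene identifiers will find no genes — "
            "supply a custom GMT in your identifier namespace"
        )
        warnings.append(msg)
        logger.warning(msg)
    return warnings
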