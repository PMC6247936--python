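"""Readers and writers for KEGG-dialect flat files and ``.list`` mappings.

The flat-file dialect is field-tagged: a field starts on a line whose
first column holds an uppercase keyword left-justified in a 12-character
gutter; continuation lines are indented by 12 spaces; ``///`` on its own
line closes a record.  ``.list`` files are two-column TSV mappings between
two KEGG databases, with values optionally prefixed by a database tag
(``ko:K00001``, ``ec:1.1.1.1``, ``gn:T00001``); the prefixes are stripped
on load.

No KEGG data ships with this package: the same dialects are emitted by
:mod:`modq.synth`, so everything is testable on synthetic files.  Readers
transparently accept gzip-compressed files (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .completeness import GeneSet
from .errors import MalformedLine, MalformedRecord, ParseWarning, UnknownGenomeWarning
from .grammar import (
    DefinitionAST,
    GeneToken,
    Namespace,
    parse_definition,
)
from .translate import MappingTable

__all__ = [
    "FIELD_WIDTH",
    "FlatFileRecord",
    "ModuleRecord",
    "GenomeRecord",
    "parse_flat_file",
    "write_flat_file",
    "parse_list_file",
    "write_list_file",
    "load_module_db",
    "write_module_db",
    "load_genome_db",
    "write_genome_db",
]

FIELD_WIDTH = 12  # KEGG keyword gutter width

_PREFIX_NAMESPACES = {"ko": "ko", "ec": "ec", "gn": "genome", "md": "module"}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


@dataclass
class FlatFileRecord:
    """One field-tagged record: ordered map of field name to value lines."""

    fields: dict[str, list[str]] = field(default_factory=dict)

    def add(self, name: str, value: str) -> None:
        self.fields.setdefault(name, []).append(value)

    def first(self, name: str, default: str = "") -> str:
        vals = self.fields.get(name)
        return vals[0] if vals else default

    def joined(self, name: str, sep: str = " ") -> str:
        return sep.join(self.fields.get(name, []))

    @property
    def entry_id(self) -> str:
        """First whitespace token of the ENTRY field."""
        return self.first("ENTRY").split()[0]


def parse_flat_file(path, field_width: int = FIELD_WIDTH) -> list[FlatFileRecord]:
    """Parse a KEGG-dialect flat file into records.

    Field names are detected as uppercase keywords in the first
    ``field_width`` columns; indented lines continue the current field.  A
    trailing record not closed by ``///`` is kept with a warning; a record
    without an ENTRY field raises :class:`MalformedRecord`.
    """
    records: list[FlatFileRecord] = []
    current: FlatFileRecord | None = None
    current_field: str | None = None

    def close(rec: FlatFileRecord | None) -> None:
        if rec is None:
            return
        if "ENTRY" not in rec.fields:
            raise MalformedRecord("record lacks an ENTRY field")
        records.append(rec)

    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.strip() == "///":
                close(current)
                current = None
                current_field = None
                continue
            if not line.strip():
                continue
            if line.startswith(" "):
                if current is None or current_field is None:
                    raise MalformedRecord(
                        "continuation line outside any field"
                    )
                current.add(current_field, line[field_width:].rstrip())
                continue
            keyword = line[:field_width].strip()
            if not keyword or not keyword[0].isupper():
                raise MalformedRecord(f"unrecognized line {line!r}")
            if current is None:
                current = FlatFileRecord()
            current_field = keyword
            current.add(keyword, line[field_width:].rstrip())
    if current is not None:
        warnings.warn(
            "file ends inside a record (missing '///'); record kept",
            ParseWarning,
            stacklevel=2,
        )
        close(current)
    if not records:
        warnings.warn("no records found", ParseWarning, stacklevel=2)
    return records


def write_flat_file(records: Iterable[FlatFileRecord], path,
                    field_width: int = FIELD_WIDTH) -> None:
    """Write records back in the canonical flat-file dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            for name, values in rec.fields.items():
                for i, value in enumerate(values):
                    gutter = name.ljust(field_width) if i == 0 else " " * field_width
                    fh.write(f"{gutter}{value}\n")
            fh.write("///\n")


@dataclass
class ModuleRecord:
    """A functional module: identity, classification and parsed definition."""

    module_id: str
    name: str
    class_levels: list[str]
    definition_text: str
    ast: DefinitionAST

    @classmethod
    def from_flat_record(
        cls, rec: FlatFileRecord, namespace: Namespace = Namespace.ORTHOLOG
    ) -> "ModuleRecord":
        definition = rec.joined("DEFINITION")
        return cls(
            module_id=rec.entry_id,
            name=rec.first("NAME"),
            class_levels=[
                part for part in rec.joined("CLASS").split("; ") if part
            ],
            definition_text=definition,
            ast=parse_definition(definition, namespace),
        )

    def to_flat_record(self) -> FlatFileRecord:
        rec = FlatFileRecord()
        rec.add("ENTRY", f"{self.module_id}            Module")
        rec.add("NAME", self.name)
        rec.add("DEFINITION", self.definition_text)
        if self.class_levels:
            rec.add("CLASS", "; ".join(self.class_levels))
        return rec


@dataclass
class GenomeRecord:
    """A genome: T-number identity, organism name, taxonomy and its gene
    complement as an ortholog gene set."""

    genome_id: str
    organism_name: str
    taxonomy: list[str]
    genes: GeneSet

    def to_flat_record(self) -> FlatFileRecord:
        rec = FlatFileRecord()
        rec.add("ENTRY", f"{self.genome_id}            Complete Genome")
        rec.add("NAME", self.organism_name)
        if self.taxonomy:
            rec.add("TAXONOMY", "; ".join(self.taxonomy))
        return rec


def load_module_db(
    path, namespace: Namespace = Namespace.ORTHOLOG
) -> list[ModuleRecord]:
    """Load a module flat file into fully parsed module records."""
    return [
        ModuleRecord.from_flat_record(rec, namespace)
        for rec in parse_flat_file(path)
    ]


def write_module_db(modules: Iterable[ModuleRecord], path) -> None:
    write_flat_file((m.to_flat_record() for m in modules), path)


def _strip_prefix(value: str) -> tuple[str | None, str]:
    if ":" in value:
        prefix, rest = value.split(":", 1)
        return prefix, rest
    return None, value


def parse_list_file(
    path,
    from_namespace: str | None = None,
    to_namespace: str | None = None,
) -> MappingTable:
    """Parse a two-column ``.list`` mapping file.

    Database prefixes (``ko:``, ``ec:`` ...) are stripped and, when
    present, used to infer the namespaces unless the caller declares them.
    Duplicate pairs collapse (the binary matrix is 0/1).  A line without
    exactly two tab-separated columns raises :class:`MalformedLine` with
    its line number.
    """
    pairs: set[tuple[str, str]] = set()
    seen_from = seen_to = None
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise MalformedLine(
                    f"line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            pa, a = _strip_prefix(cols[0])
            pb, b = _strip_prefix(cols[1])
            seen_from = seen_from or pa
            seen_to = seen_to or pb
            pairs.add((a, b))
    from_ns = from_namespace or _PREFIX_NAMESPACES.get(seen_from or "", seen_from) or "from"
    to_ns = to_namespace or _PREFIX_NAMESPACES.get(seen_to or "", seen_to) or "to"
    return MappingTable(from_ns, to_ns, frozenset(pairs))


def write_list_file(
    mapping: MappingTable,
    path,
    from_prefix: str | None = None,
    to_prefix: str | None = None,
) -> None:
    """Write a mapping as a sorted two-column ``.list`` file."""
    fp = f"{from_prefix}:" if from_prefix else ""
    tp = f"{to_prefix}:" if to_prefix else ""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(mapping.pairs):
            fh.write(f"{fp}{a}\t{tp}{b}\n")


def load_genome_db(genome_path, genome_gene_list_path) -> list[GenomeRecord]:
    """Load genomes from a genome flat file joined with a genome-to-ortholog
    ``.list`` mapping.

    Genomes referenced by the mapping but absent from the flat file produce
    an :class:`UnknownGenomeWarning` (not fatal); genomes with no mapped
    genes are kept with an empty gene set and a warning.
    """
    recs = parse_flat_file(genome_path)
    mapping = parse_list_file(genome_gene_list_path)
    genes_by_genome: dict[str, set[GeneToken]] = {}
    for gid, k in mapping.pairs:
        genes_by_genome.setdefault(gid, set()).add(
            GeneToken(Namespace.ORTHOLOG, k)
        )
    known_ids = {rec.entry_id for rec in recs}
    for gid in sorted(set(genes_by_genome) - known_ids):
        warnings.warn(
            f"mapping references unknown genome {gid}",
            UnknownGenomeWarning,
            stacklevel=2,
        )
    genomes: list[GenomeRecord] = []
    for rec in recs:
        gid = rec.entry_id
        members = genes_by_genome.get(gid, set())
        if not members:
            warnings.warn(
                f"genome {gid} has no mapped genes",
                UnknownGenomeWarning,
                stacklevel=2,
            )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                organism_name=rec.first("NAME"),
                taxonomy=[
                    t for t in rec.joined("TAXONOMY").split("; ") if t
                ],
                genes=GeneSet(Namespace.ORTHOLOG, frozenset(members)),
            )
        )
    return genomes


def write_genome_db(genomes: Iterable[GenomeRecord], genome_path,
                    genome_gene_list_path) -> None:
    """Write the genome flat file and the genome-to-ortholog ``.list``."""
    genomes = list(genomes)
    write_flat_file((g.to_flat_record() for g in genomes), genome_path)
    pairs = frozenset(
        (g.genome_id, tok.identifier)
        for g in genomes
        for tok in g.genes.members
    )
    write_list_file(
        MappingTable("genome", "ko", pairs),
        genome_gene_list_path,
        from_prefix="gn",
        to_prefix="ko",
    )
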