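"""Readers and writers for the tabular input formats.

Four on-disk formats are supported, all plain TSV (the link file may be
gzip-compressed):

* chemical-protein links with an integer confidence score in [0, 1000]
  (header names a chemical, a protein and a score column);
* chemical alias table mapping names / CAS numbers to chemical IDs;
* protein -> gene mapping (protein_id, gene_symbol, gene_id, gene_name);
* GMT gene-set catalogs (term_id TAB description TAB gene1 TAB gene2 ...).
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from .errors import (
    AmbiguousAliasError,
    ChemicalNotFoundError,
    FormatError,
)

logger = logging.getLogger(__name__)

SCORE_MIN = 0
SCORE_MAX = 1000

__all__ = [
    "InteractionRecord",
    "InteractionTable",
    "ChemicalAliasIndex",
    "GeneInfo",
    "ProteinGeneMap",
    "AnnotationCatalog",
    "read_stitch_links",
    "write_stitch_links",
    "read_alias_table",
    "resolve_chemical",
    "read_gmt",
    "write_gmt",
    "read_protein_gene_map",
    "normalize_alias",
]


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One chemical-protein link with its integrated confidence score."""

    chemical_id: str
    protein_id: str
    combined_score: int

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.protein_id:
            raise FormatError("chemical_id and protein_id must be non-empty")
        if not SCORE_MIN <= self.combined_score <= SCORE_MAX:
            raise FormatError(
                f"combined_score {self.combined_score} outside "
                f"[{SCORE_MIN}, {SCORE_MAX}]"
            )


@dataclass
class InteractionTable:
    """Deduplicated collection of chemical-protein links.

    Duplicate (chemical_id, protein_id) pairs are collapsed keeping the
    maximum score, so a pair occurs at most once.
    """

    records: list[InteractionRecord]
    source_version: str = ""

    @classmethod
    def from_records(
        cls, records: Iterable[InteractionRecord], source_version: str = ""
    ) -> "InteractionTable":
        """Build a table, collapsing duplicate pairs to the max score."""
        best: dict[tuple[str, str], int] = {}
        for rec in records:
            key = (rec.chemical_id, rec.protein_id)
            if key not in best or rec.combined_score > best[key]:
                best[key] = rec.combined_score
        collapsed = [
            InteractionRecord(c, p, s) for (c, p), s in sorted(best.items())
        ]
        return cls(records=collapsed, source_version=source_version)

    def chemicals(self) -> set[str]:
        return {r.chemical_id for r in self.records}

    def for_chemical(self, chemical_id: str) -> list[InteractionRecord]:
        return [r for r in self.records if r.chemical_id == chemical_id]

    def filter(self, chemical_ids: set[str]) -> "InteractionTable":
        return InteractionTable(
            records=[r for r in self.records if r.chemical_id in chemical_ids],
            source_version=self.source_version,
        )

    def __len__(self) -> int:
        return len(self.records)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8", newline="")
    return open(path, "rt", encoding="utf-8", newline="")


def _find_column(header: list[str], wanted: tuple[str, ...], path: Path) -> int:
    lowered = [h.strip().lower() for h in header]
    for name in wanted:
        if name in lowered:
            return lowered.index(name)
    raise FormatError(
        f"{path}: header {header!r} lacks a column named one of {wanted}"
    )


def read_stitch_links(
    path: str | Path, chemical_filter: set[str] | None = None
) -> InteractionTable:
    """Read a chemical-protein link TSV (optionally gzipped).

    Parameters
    ----------
    path:
        TSV with a header line naming chemical, protein and score columns.
    chemical_filter:
        If given, only rows whose chemical_id is in this set are kept.

    Duplicate (chemical, protein) pairs collapse to the maximum score.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        i_chem = _find_column(header, ("chemical", "chemical_id", "item_id_a"), path)
        i_prot = _find_column(header, ("protein", "protein_id", "item_id_b"), path)
        i_score = _find_column(header, ("combined_score", "score"), path)
        n_cols = max(i_chem, i_prot, i_score) + 1
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_cols:
                raise FormatError(f"{path}:{lineno}: expected {n_cols} fields, got {len(row)}")
            chem = row[i_chem].strip()
            prot = row[i_prot].strip()
            raw_score = row[i_score].strip()
            try:
                score = int(raw_score)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: combined_score {raw_score!r} is not an integer"
                ) from None
            if not SCORE_MIN <= score <= SCORE_MAX:
                raise FormatError(
                    f"{path}:{lineno}: combined_score {score} outside "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )
            if chemical_filter is not None and chem not in chemical_filter:
                continue
            try:
                records.append(InteractionRecord(chem, prot, score))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return InteractionTable.from_records(records)


def write_stitch_links(table: InteractionTable, path: str | Path) -> None:
    """Write a link table back to TSV (round-trips through read_stitch_links)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("chemical\tprotein\tcombined_score\n")
        for rec in sorted(table.records):
            handle.write(f"{rec.chemical_id}\t{rec.protein_id}\t{rec.combined_score}\n")


def normalize_alias(alias: str) -> str:
    """Deterministic alias normalization: trim whitespace, case-fold.

    CAS numbers contain no letters so they are effectively kept verbatim
    apart from trimming.
    """
    return alias.strip().casefold()


@dataclass
class ChemicalAliasIndex:
    """Exact-match lookup from normalized alias to chemical identifier."""

    entries: dict[str, str] = field(default_factory=dict)
    display_names: dict[str, str] = field(default_factory=dict)
    conflicts: dict[str, set[str]] = field(default_factory=dict)

    def add(self, chemical_id: str, alias: str) -> None:
        key = normalize_alias(alias)
        if not key:
            return
        if key in self.conflicts:
            self.conflicts[key].add(chemical_id)
            return
        if key in self.entries and self.entries[key] != chemical_id:
            self.conflicts[key] = {self.entries.pop(key), chemical_id}
            return
        self.entries[key] = chemical_id
        # first non-numeric alias seen becomes the display name
        if chemical_id not in self.display_names and not alias.strip()[:1].isdigit():
            self.display_names[chemical_id] = alias.strip()

    def resolve(self, query: str) -> str:
        key = normalize_alias(query)
        if key in self.conflicts:
            raise AmbiguousAliasError(query, self.conflicts[key])
        try:
            return self.entries[key]
        except KeyError:
            raise ChemicalNotFoundError(query) from None

    def display_name(self, chemical_id: str) -> str:
        return self.display_names.get(chemical_id, chemical_id)


def read_alias_table(path: str | Path) -> ChemicalAliasIndex:
    """Read a two-column TSV of (chemical_id, alias) rows."""
    path = Path(path)
    index = ChemicalAliasIndex()
    n_rows = 0
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            index.add(row[0].strip(), row[1])
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: empty alias table")
    for alias, candidates in index.conflicts.items():
        logger.warning(
            "alias %r maps to multiple chemicals: %s",
            alias,
            ", ".join(sorted(candidates)),
        )
    return index


def resolve_chemical(query: str, index: ChemicalAliasIndex) -> str:
    """Resolve a name or CAS number to a chemical_id (exact match only)."""
    return index.resolve(query)


@dataclass(frozen=True)
class GeneInfo:
    gene_symbol: str
    gene_id: str
    gene_name: str


@dataclass
class ProteinGeneMap:
    """Unambiguous mapping protein_id -> gene annotation."""

    entries: dict[str, GeneInfo] = field(default_factory=dict)

    def get(self, protein_id: str) -> GeneInfo | None:
        return self.entries.get(protein_id)

    def __len__(self) -> int:
        return len(self.entries)


def read_protein_gene_map(path: str | Path) -> ProteinGeneMap:
    """Read a 4-column TSV (protein_id, gene_symbol, gene_id, gene_name).

    Duplicate consistent rows are deduplicated silently; conflicting rows
    for the same protein are an error.
    """
    path = Path(path)
    entries: dict[str, GeneInfo] = {}
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            protein_id = row[0].strip()
            info = GeneInfo(row[1].strip(), row[2].strip(), row[3].strip())
            existing = entries.get(protein_id)
            if existing is not None and existing != info:
                raise FormatError(
                    f"{path}:{lineno}: conflicting mapping for protein "
                    f"{protein_id!r}: {existing} vs {info}"
                )
            entries[protein_id] = info
    return ProteinGeneMap(entries=entries)


@dataclass
class AnnotationCatalog:
    """One namespace of term -> gene-set annotations.

    The background universe is derived, never stored: it is exactly the
    union of all term gene sets.
    """

    namespace: str
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise FormatError(
                    f"catalog {self.namespace!r}: term {term_id!r} has no genes"
                )

    @property
    def background(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def description(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


def read_gmt(path: str | Path, namespace: str) -> AnnotationCatalog:
    """Read a GMT gene-set file into an annotation catalog.

    Lines with zero member genes are dropped with a warning; a term
    appearing on several lines has its gene sets merged by union.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs at least term_id and description"
                )
            term_id, description = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("%s:%d: term %r has no genes; dropped", path, lineno, term_id)
                continue
            if term_id in terms:
                logger.warning("%s:%d: term %r listed twice; gene sets merged", path, lineno, term_id)
                old_desc, old_genes = terms[term_id]
                terms[term_id] = (old_desc or description, old_genes | genes)
            else:
                terms[term_id] = (description, genes)
    if not terms:
        raise FormatError(f"{path}: no usable gene sets")
    return AnnotationCatalog(namespace=namespace, terms=terms)


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Write a catalog as GMT (round-trips through read_gmt)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        for term_id in sorted(catalog.terms):
            description, genes = catalog.terms[term_id]
            handle.write("\t".join([term_id, description, *sorted(genes)]) + "\n")
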