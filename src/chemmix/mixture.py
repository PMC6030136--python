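"""Mixture-interaction analysis.

Given 2-4 chemicals and a loaded data bundle, this module extracts each
chemical's confidence-filtered target genes, partitions targets and
per-namespace significant terms into disjoint Venn regions, computes the
product-form joint p-value for terms significant in every chemical, and
runs union-based overall enrichment for the mixture acting as a single
exposure.

The joint p-value for a term shared by all n chemicals is the product of
the per-chemical BH-adjusted p-values; it is tracked both directly and in
log10 space so extremely small products keep an exact magnitude even when
the direct product underflows to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrichment import DEFAULT_ALPHA, EnrichmentTable, enrich
from .errors import ChemicalNotFoundError, ContractError, DomainError
from .io import (
    AnnotationCatalog,
    ChemicalAliasIndex,
    InteractionTable,
    ProteinGeneMap,
    read_alias_table,
    read_gmt,
    read_protein_gene_map,
    read_stitch_links,
    resolve_chemical,
)

__all__ = [
    "ConfidenceLevel",
    "CONFIDENCE_LEVELS",
    "get_confidence_level",
    "TargetSet",
    "VennRegions",
    "JointPValue",
    "MixtureReport",
    "DataBundle",
    "select_targets",
    "venn_partition",
    "joint_pvalue",
    "shared_term_analysis",
    "overall_enrichment",
    "analyze_mixture",
]

MIN_SETS = 2
MAX_SETS = 4


@dataclass(frozen=True)
class ConfidenceLevel:
    """Named minimum combined-score threshold for keeping a link."""

    name: str
    min_score: int


# STITCH convention: low/medium/high confidence cutoffs.
CONFIDENCE_LEVELS: dict[str, ConfidenceLevel] = {
    "low": ConfidenceLevel("low", 150),
    "medium": ConfidenceLevel("medium", 400),
    "high": ConfidenceLevel("high", 700),
}


def get_confidence_level(level: str | int | ConfidenceLevel) -> ConfidenceLevel:
    """Resolve a level name, explicit integer threshold, or pass-through."""
    if isinstance(level, ConfidenceLevel):
        return level
    if isinstance(level, int):
        return ConfidenceLevel(f"custom({level})", level)
    try:
        return CONFIDENCE_LEVELS[level]
    except KeyError:
        raise ContractError(
            f"unknown confidence level {level!r}; expected one of "
            f"{sorted(CONFIDENCE_LEVELS)} or an integer threshold"
        ) from None


@dataclass
class TargetSet:
    """One chemical's confidence-filtered interacting genes.

    ``protein_details`` keeps per-protein rows (protein_id, gene_symbol,
    gene_id, gene_name, combined_score) for report output; unmapped
    proteins are retained in ``unmapped_proteins`` but excluded from
    ``genes``.
    """

    chemical_id: str
    genes: set[str] = field(default_factory=set)
    per_gene_score: dict[str, int] = field(default_factory=dict)
    unmapped_proteins: set[str] = field(default_factory=set)
    protein_details: list[tuple[str, str, str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genes != set(self.per_gene_score):
            raise ContractError("genes and per_gene_score must share key sets")


def select_targets(
    table: InteractionTable,
    chemical_id: str,
    level: ConfidenceLevel,
    protein_gene_map: ProteinGeneMap,
) -> TargetSet:
    """Extract a chemical's targets at a confidence level.

    Keeps links with combined_score >= level.min_score and maps proteins
    to gene symbols; several proteins mapping to one gene collapse to the
    maximum score. A chemical absent from the table (pre-filter) is an
    error, distinct from an empty result after filtering.
    """
    links = table.for_chemical(chemical_id)
    if not links:
        raise ChemicalNotFoundError(
            chemical_id, f"chemical {chemical_id!r} has no links in the table"
        )
    per_gene_score: dict[str, int] = {}
    unmapped: set[str] = set()
    details: list[tuple[str, str, str, str, int]] = []
    for rec in links:
        if rec.combined_score < level.min_score:
            continue
        info = protein_gene_map.get(rec.protein_id)
        if info is None:
            unmapped.add(rec.protein_id)
            continue
        details.append(
            (rec.protein_id, info.gene_symbol, info.gene_id, info.gene_name,
             rec.combined_score)
        )
        prev = per_gene_score.get(info.gene_symbol)
        if prev is None or rec.combined_score > prev:
            per_gene_score[info.gene_symbol] = rec.combined_score
    details.sort(key=lambda row: (row[1], row[0]))
    return TargetSet(
        chemical_id=chemical_id,
        genes=set(per_gene_score),
        per_gene_score=per_gene_score,
        unmapped_proteins=unmapped,
        protein_details=details,
    )


@dataclass
class VennRegions:
    """Disjoint partition of 2-4 labeled sets into 2^n - 1 regions.

    ``regions`` maps every non-empty subset of labels (as a frozenset) to
    the elements belonging to exactly those sets; empty regions are
    present with empty member sets.
    """

    labels: list[str]
    regions: dict[frozenset[str], set[str]]

    def region(self, *labels: str) -> set[str]:
        return self.regions[frozenset(labels)]

    @property
    def full_intersection(self) -> set[str]:
        return self.regions[frozenset(self.labels)]

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return out

    def to_json_dict(self) -> dict[str, list[str]]:
        """Serializable form: sorted '+'-joined label keys, sorted members."""
        out: dict[str, list[str]] = {}
        for key in sorted(self.regions, key=lambda s: (len(s), "+".join(sorted(s)))):
            out["+".join(sorted(key))] = sorted(self.regions[key])
        return out


def venn_partition(labeled_sets: Mapping[str, Iterable[str]]) -> VennRegions:
    """Assign each element of the union to its exact membership region."""
    labels = list(labeled_sets)
    if not MIN_SETS <= len(labels) <= MAX_SETS:
        raise ContractError(
            f"venn partition needs between {MIN_SETS} and {MAX_SETS} sets, "
            f"got {len(labels)}"
        )
    if len(set(labels)) != len(labels):
        raise ContractError("set labels must be unique")
    sets = {label: set(members) for label, members in labeled_sets.items()}
    regions: dict[frozenset[str], set[str]] = {}
    n = len(labels)
    for mask in range(1, 2**n):
        key = frozenset(labels[i] for i in range(n) if mask >> i & 1)
        regions[key] = set()
    union: set[str] = set()
    for members in sets.values():
        union |= members
    for element in union:
        key = frozenset(label for label in labels if element in sets[label])
        regions[key].add(element)
    return VennRegions(labels=labels, regions=regions)


@dataclass
class JointPValue:
    """Product-form joint p-value of one term shared by all chemicals.

    ``joint_p`` is the direct product of the per-chemical adjusted
    p-values (clamped to 0 on underflow); ``log10_joint_p`` is the sum of
    log10 values and stays exact through underflow. A zero input
    propagates joint_p = 0 with a -inf log10 sentinel and sets
    ``has_zero_input``.
    """

    term_id: str
    per_chemical_adj_p: dict[str, float]
    joint_p: float
    log10_joint_p: float
    has_zero_input: bool = False

    @property
    def n_chemicals(self) -> int:
        return len(self.per_chemical_adj_p)


def joint_pvalue(
    per_chemical_adj_p: Mapping[str, float], term_id: str = ""
) -> JointPValue:
    """Combine per-chemical adjusted p-values into their product."""
    if not per_chemical_adj_p:
        raise ContractError("need at least one chemical")
    values = dict(per_chemical_adj_p)
    for chem, p in values.items():
        if not (0.0 <= p <= 1.0) or not math.isfinite(p):
            raise DomainError(f"adjusted p for {chem!r} must lie in [0, 1], got {p}")
    if any(p == 0.0 for p in values.values()):
        return JointPValue(
            term_id=term_id, per_chemical_adj_p=values,
            joint_p=0.0, log10_joint_p=-math.inf, has_zero_input=True,
        )
    log10_joint = math.fsum(math.log10(p) for p in values.values())
    product = 1.0
    for p in values.values():
        product *= p
    return JointPValue(
        term_id=term_id, per_chemical_adj_p=values,
        joint_p=product, log10_joint_p=log10_joint,
    )


def shared_term_analysis(
    tables: Mapping[str, EnrichmentTable],
) -> tuple[VennRegions, list[JointPValue]]:
    """Venn-partition significant terms and score the shared ones.

    ``tables`` maps chemical label -> that chemical's enrichment table for
    one namespace. Terms significant in every chemical (the
    full-intersection region) get a joint p-value from each chemical's own
    adjusted p; results are sorted by joint_p ascending, then term_id.
    """
    if not MIN_SETS <= len(tables) <= MAX_SETS:
        raise ContractError(
            f"shared-term analysis needs {MIN_SETS}-{MAX_SETS} chemicals, "
            f"got {len(tables)}"
        )
    namespaces = {t.namespace for t in tables.values()}
    if len(namespaces) != 1:
        raise ContractError(f"tables span multiple namespaces: {sorted(namespaces)}")
    sig_sets = {label: table.significant_terms() for label, table in tables.items()}
    venn = venn_partition(sig_sets)
    joints: list[JointPValue] = []
    for term_id in venn.full_intersection:
        per_chem = {
            label: tables[label].record_for(term_id).p_adj for label in tables
        }
        joints.append(joint_pvalue(per_chem, term_id=term_id))
    joints.sort(key=lambda j: (j.log10_joint_p, j.term_id))
    return venn, joints


def overall_enrichment(
    target_sets: Sequence[TargetSet],
    catalog: AnnotationCatalog,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentTable:
    """Enrichment of the union of all target sets (the mixture as one)."""
    if not target_sets:
        raise ContractError("need at least one target set")
    union: set[str] = set()
    for ts in target_sets:
        union |= ts.genes
    return enrich(union, catalog, alpha=alpha, label="union")


@dataclass
class DataBundle:
    """Everything one analysis needs, loaded and indexed."""

    interactions: InteractionTable
    aliases: ChemicalAliasIndex
    protein_gene_map: ProteinGeneMap
    catalogs: dict[str, AnnotationCatalog]

    @classmethod
    def load(
        cls,
        links_path: str | Path,
        alias_path: str | Path,
        map_path: str | Path,
        gmt_paths: Mapping[str, str | Path],
    ) -> "DataBundle":
        return cls(
            interactions=read_stitch_links(links_path),
            aliases=read_alias_table(alias_path),
            protein_gene_map=read_protein_gene_map(map_path),
            catalogs={
                ns: read_gmt(path, ns) for ns, path in gmt_paths.items()
            },
        )


@dataclass
class MixtureReport:
    """Full output of one mixture analysis."""

    chemicals: list[str]
    labels: list[str]
    confidence: ConfidenceLevel
    alpha: float
    target_sets: dict[str, TargetSet]
    target_venn: VennRegions
    per_chemical_enrichment: dict[tuple[str, str], EnrichmentTable]
    term_venn: dict[str, VennRegions]
    shared_terms: dict[str, list[JointPValue]]
    overall_enrichment: dict[str, EnrichmentTable]

    def label_for(self, chemical_id: str) -> str:
        return self.labels[self.chemicals.index(chemical_id)]


def analyze_mixture(
    chemical_queries: Sequence[str],
    bundle: DataBundle,
    level: str | int | ConfidenceLevel = "medium",
    namespaces: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> MixtureReport:
    """Run the full pipeline for 2-4 chemicals.

    Resolves queries, extracts targets, partitions targets into Venn
    regions, enriches per chemical per namespace, partitions significant
    terms and computes joint p-values, and finally runs union-based
    overall enrichment. A chemical with zero targets after filtering is
    retained with empty outputs. Deterministic for fixed inputs.
    """
    if not MIN_SETS <= len(chemical_queries) <= MAX_SETS:
        raise ContractError(
            f"between {MIN_SETS} and {MAX_SETS} chemicals can be analyzed, "
            f"got {len(chemical_queries)}"
        )
    conf = get_confidence_level(level)
    chemicals = [resolve_chemical(q, bundle.aliases) for q in chemical_queries]
    if len(set(chemicals)) != len(chemicals):
        raise ContractError(f"queries resolve to duplicate chemicals: {chemicals}")
    labels = [bundle.aliases.display_name(c) for c in chemicals]
    if len(set(labels)) != len(labels):  # fall back to IDs on name collision
        labels = list(chemicals)

    if namespaces is None:
        namespaces = sorted(bundle.catalogs)
    for ns in namespaces:
        if ns not in bundle.catalogs:
            raise ContractError(f"no catalog loaded for namespace {ns!r}")

    target_sets = {
        chem: select_targets(bundle.interactions, chem, conf, bundle.protein_gene_map)
        for chem in chemicals
    }
    target_venn = venn_partition(
        {label: target_sets[chem].genes for chem, label in zip(chemicals, labels)}
    )

    per_chemical_enrichment: dict[tuple[str, str], EnrichmentTable] = {}
    term_venn: dict[str, VennRegions] = {}
    shared_terms: dict[str, list[JointPValue]] = {}
    overall: dict[str, EnrichmentTable] = {}
    for ns in namespaces:
        catalog = bundle.catalogs[ns]
        tables: dict[str, EnrichmentTable] = {}
        for chem, label in zip(chemicals, labels):
            table = enrich(target_sets[chem].genes, catalog, alpha=alpha, label=label)
            per_chemical_enrichment[(chem, ns)] = table
            tables[label] = table
        venn, joints = shared_term_analysis(tables)
        term_venn[ns] = venn
        shared_terms[ns] = joints
        overall[ns] = overall_enrichment(
            [target_sets[c] for c in chemicals], catalog, alpha=alpha
        )
    return MixtureReport(
        chemicals=chemicals,
        labels=labels,
        confidence=conf,
        alpha=alpha,
        target_sets=target_sets,
        target_venn=target_venn,
        per_chemical_enrichment=per_chemical_enrichment,
        term_venn=term_venn,
        shared_terms=shared_terms,
        overall_enrichment=overall,
    )
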