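"""Seeded synthetic data-bundle generator.

Produces an internally consistent set of inputs — chemical-protein links,
chemical aliases, a protein->gene map and per-namespace GMT catalogs —
with planted shared target genes and planted co-enriched terms, so the
whole pipeline is testable offline with known ground truth.

Planted links always score in [700, 1000] so they survive the "high"
confidence filter; filler links score in [150, 1000] (or per a
configurable band distribution) so every confidence level is exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io import (
    AnnotationCatalog,
    ChemicalAliasIndex,
    GeneInfo,
    InteractionRecord,
    InteractionTable,
    ProteinGeneMap,
    write_gmt,
    write_stitch_links,
)
from .mixture import DataBundle, analyze_mixture

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "DEFAULT_CONFIG",
    "build_bundle",
    "generate_fixture",
    "expected_planted_significance",
    "PlantedTermCheck",
    "PlantedSignificanceReport",
]

SCORE_BANDS = {"low": (150, 399), "medium": (400, 699), "high": (700, 1000)}
PLANTED_SCORE_RANGE = (700, 1000)
FILLER_SCORE_RANGE = (150, 1000)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for one synthetic bundle; deterministic given ``seed``."""

    seed: int = 42
    n_chemicals: int = 2
    n_background_genes: int = 200
    n_terms_per_namespace: int = 20
    term_size_range: tuple[int, int] = (8, 15)
    targets_per_chemical: int = 30
    n_planted_shared_targets: int = 3
    planted_terms: tuple[tuple[str, float], ...] = (("DO", 1.0),)
    namespaces: tuple[str, ...] = ("GO", "KEGG", "DO")
    score_distribution: tuple[tuple[str, float], ...] | None = None

    def validate(self) -> None:
        if self.n_chemicals < 2 or self.n_chemicals > 4:
            raise ConfigError("n_chemicals must be 2-4")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad term_size_range {self.term_size_range}")
        if hi > self.n_background_genes:
            raise ConfigError(
                f"max term size {hi} exceeds background of {self.n_background_genes} genes"
            )
        if self.targets_per_chemical > self.n_background_genes:
            raise ConfigError("targets_per_chemical exceeds background size")
        if self.n_planted_shared_targets > self.targets_per_chemical:
            raise ConfigError(
                "n_planted_shared_targets must not exceed targets_per_chemical"
            )
        for ns, fraction in self.planted_terms:
            if ns not in self.namespaces:
                raise ConfigError(f"planted namespace {ns!r} not in {self.namespaces}")
            if not (0.0 < fraction <= 1.0):
                raise ConfigError(f"planted fraction must be in (0, 1], got {fraction}")
        if self.score_distribution is not None:
            for band, weight in self.score_distribution:
                if band not in SCORE_BANDS:
                    raise ConfigError(f"unknown score band {band!r}")
                if weight < 0:
                    raise ConfigError("score band weights must be >= 0")


DEFAULT_CONFIG = FixtureConfig()


@dataclass
class GroundTruth:
    """What the generator planted, for assertions downstream."""

    chemical_ids: list[str]
    chemical_names: dict[str, str]
    planted_shared_genes: list[str]
    planted_term_ids: dict[str, str]  # namespace -> term_id
    target_genes: dict[str, list[str]]  # chemical_id -> all target genes


@dataclass
class MemoryBundle:
    """In-memory form of a generated bundle plus its ground truth."""

    config: FixtureConfig
    interactions: InteractionTable
    aliases: ChemicalAliasIndex
    alias_rows: list[tuple[str, str]]
    protein_gene_map: ProteinGeneMap
    catalogs: dict[str, AnnotationCatalog]
    truth: GroundTruth

    def as_data_bundle(self) -> DataBundle:
        return DataBundle(
            interactions=self.interactions,
            aliases=self.aliases,
            protein_gene_map=self.protein_gene_map,
            catalogs=self.catalogs,
        )


@dataclass
class FixtureBundle:
    """Paths to generated files plus the manifest (config + ground truth)."""

    root: Path
    links_path: Path
    alias_path: Path
    map_path: Path
    gmt_paths: dict[str, Path]
    manifest_path: Path
    manifest: dict

    def load(self) -> DataBundle:
        return DataBundle.load(
            self.links_path, self.alias_path, self.map_path, self.gmt_paths
        )


def _draw_score(rng: np.random.Generator, config: FixtureConfig) -> int:
    if config.score_distribution is None:
        lo, hi = FILLER_SCORE_RANGE
        return int(rng.integers(lo, hi + 1))
    bands = [b for b, _ in config.score_distribution]
    weights = np.array([w for _, w in config.score_distribution], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ConfigError("score band weights sum to zero")
    band = bands[int(rng.choice(len(bands), p=weights / total))]
    lo, hi = SCORE_BANDS[band]
    return int(rng.integers(lo, hi + 1))


def build_bundle(config: FixtureConfig = DEFAULT_CONFIG) -> MemoryBundle:
    """Generate a bundle in memory; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_background_genes + 1)]
    proteins = {g: f"9606.ENSP{i:08d}" for i, g in enumerate(genes, start=1)}
    pg_entries = {
        proteins[g]: GeneInfo(g, str(10000 + i), f"{g} protein")
        for i, g in enumerate(genes, start=1)
    }

    catalogs: dict[str, AnnotationCatalog] = {}
    lo, hi = config.term_size_range
    for ns in config.namespaces:
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for j in range(1, config.n_terms_per_namespace + 1):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(config.n_background_genes, size=size, replace=False)
            terms[f"{ns}:{j:04d}"] = (
                f"synthetic {ns} term {j}",
                frozenset(genes[m] for m in members),
            )
        catalogs[ns] = AnnotationCatalog(namespace=ns, terms=terms)

    planted_term_ids: dict[str, str] = {}
    planted_term_genes: set[str] = set()
    for ns, fraction in config.planted_terms:
        term_idx = int(rng.integers(1, config.n_terms_per_namespace + 1))
        term_id = f"{ns}:{term_idx:04d}"
        planted_term_ids[ns] = term_id
        term_genes = sorted(catalogs[ns].genes(term_id))
        n_pick = max(1, math.ceil(fraction * len(term_genes)))
        picked = rng.choice(len(term_genes), size=n_pick, replace=False)
        planted_term_genes.update(term_genes[i] for i in sorted(picked))

    shared_idx = rng.choice(
        config.n_background_genes, size=config.n_planted_shared_targets, replace=False
    )
    planted_shared = sorted(genes[i] for i in shared_idx)

    chemical_ids = [f"CIDm{i:08d}" for i in range(1, config.n_chemicals + 1)]
    chemical_names = {cid: f"chem{i}" for i, cid in enumerate(chemical_ids, start=1)}

    planted = set(planted_shared) | planted_term_genes
    target_genes: dict[str, list[str]] = {}
    records: list[InteractionRecord] = []
    p_lo, p_hi = PLANTED_SCORE_RANGE
    for cid in chemical_ids:
        targets = set(planted)
        remaining = [g for g in genes if g not in targets]
        n_fill = config.targets_per_chemical - len(targets)
        if n_fill > 0:
            fill_idx = rng.choice(len(remaining), size=n_fill, replace=False)
            targets.update(remaining[i] for i in sorted(fill_idx))
        target_genes[cid] = sorted(targets)
        for g in target_genes[cid]:
            if g in planted:
                score = int(rng.integers(p_lo, p_hi + 1))
            else:
                score = _draw_score(rng, config)
            records.append(InteractionRecord(cid, proteins[g], score))

    alias_rows: list[tuple[str, str]] = []
    aliases = ChemicalAliasIndex()
    for i, cid in enumerate(chemical_ids, start=1):
        name = chemical_names[cid]
        cas = f"{1000 + i}-{10 + i}-{i}"
        for alias in (name, cas):
            alias_rows.append((cid, alias))
            aliases.add(cid, alias)

    return MemoryBundle(
        config=config,
        interactions=InteractionTable.from_records(records, source_version="synthetic"),
        aliases=aliases,
        alias_rows=alias_rows,
        protein_gene_map=ProteinGeneMap(entries=pg_entries),
        catalogs=catalogs,
        truth=GroundTruth(
            chemical_ids=chemical_ids,
            chemical_names=chemical_names,
            planted_shared_genes=planted_shared,
            planted_term_ids=planted_term_ids,
            target_genes=target_genes,
        ),
    )


def generate_fixture(
    config: FixtureConfig = DEFAULT_CONFIG, outdir: str | Path = "fixture"
) -> FixtureBundle:
    """Generate a bundle and write it to ``outdir`` in the on-disk formats.

    Two runs with the same config and seed produce byte-identical files.
    The manifest records the resolved config and the planted ground truth.
    """
    mem = build_bundle(config)
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)

    links_path = root / "links.tsv"
    write_stitch_links(mem.interactions, links_path)

    alias_path = root / "aliases.tsv"
    with open(alias_path, "w", encoding="utf-8", newline="") as handle:
        for cid, alias in mem.alias_rows:
            handle.write(f"{cid}\t{alias}\n")

    map_path = root / "protein_genes.tsv"
    with open(map_path, "w", encoding="utf-8", newline="") as handle:
        for protein_id in sorted(mem.protein_gene_map.entries):
            info = mem.protein_gene_map.entries[protein_id]
            handle.write(
                f"{protein_id}\t{info.gene_symbol}\t{info.gene_id}\t{info.gene_name}\n"
            )

    gmt_paths: dict[str, Path] = {}
    for ns in config.namespaces:
        gmt_path = root / f"{ns.lower()}.gmt"
        write_gmt(mem.catalogs[ns], gmt_path)
        gmt_paths[ns] = gmt_path

    manifest = {
        "config": asdict(config),
        "ground_truth": {
            "chemical_ids": mem.truth.chemical_ids,
            "chemical_names": mem.truth.chemical_names,
            "planted_shared_genes": mem.truth.planted_shared_genes,
            "planted_term_ids": mem.truth.planted_term_ids,
            "target_genes": mem.truth.target_genes,
        },
        "files": {
            "links": links_path.name,
            "aliases": alias_path.name,
            "protein_gene_map": map_path.name,
            "gmt": {ns: p.name for ns, p in gmt_paths.items()},
        },
    }
    manifest_path = root / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8", newline="") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")

    return FixtureBundle(
        root=root,
        links_path=links_path,
        alias_path=alias_path,
        map_path=map_path,
        gmt_paths=gmt_paths,
        manifest_path=manifest_path,
        manifest=manifest,
    )


@dataclass(frozen=True)
class PlantedTermCheck:
    """Pass/fail record for one planted term."""

    namespace: str
    term_id: str
    significant_per_chemical: tuple[tuple[str, bool], ...]
    in_shared_terms: bool

    @property
    def passed(self) -> bool:
        return self.in_shared_terms and all(s for _, s in self.significant_per_chemical)


@dataclass
class PlantedSignificanceReport:
    checks: list[PlantedTermCheck] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)


def expected_planted_significance(
    config: FixtureConfig, bundle: FixtureBundle
) -> PlantedSignificanceReport:
    """Run the full analysis on a bundle and audit the planted terms.

    Every planted term must be significant for every chemical and appear
    in the shared-term list of its namespace. Returns a pass/fail report;
    empty when nothing was planted.
    """
    config.validate()
    data = bundle.load()
    truth = bundle.manifest["ground_truth"]
    queries = [truth["chemical_names"][cid] for cid in truth["chemical_ids"]]
    report = analyze_mixture(
        queries, data, level="high", namespaces=list(config.namespaces)
    )
    checks: list[PlantedTermCheck] = []
    for ns, term_id in sorted(truth["planted_term_ids"].items()):
        per_chem: list[tuple[str, bool]] = []
        for cid in report.chemicals:
            table = report.per_chemical_enrichment[(cid, ns)]
            try:
                sig = table.record_for(term_id).significant
            except KeyError:
                sig = False
            per_chem.append((cid, sig))
        in_shared = any(j.term_id == term_id for j in report.shared_terms[ns])
        checks.append(
            PlantedTermCheck(
                namespace=ns,
                term_id=term_id,
                significant_per_chemical=tuple(per_chem),
                in_shared_terms=in_shared,
            )
        )
    return PlantedSignificanceReport(checks=checks)
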