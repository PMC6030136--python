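# chemmix

Shared-target and co-enrichment analysis for chemical mixtures.

Given 2–4 chemicals and a chemogenomics data bundle (chemical–protein
links with 0–1000 confidence scores, a chemical alias table, a
protein→gene map, and one or more GMT gene-set catalogs), `chemmix`:

1. resolves each chemical by name or CAS number (exact match,
   case-insensitive);
2. extracts each chemical's target genes at a chosen confidence level
   (low ≥ 150, medium ≥ 400, high ≥ 700, or an explicit threshold);
3. partitions targets into disjoint Venn regions (2ⁿ − 1 regions for
   n chemicals);
4. tests each chemical's targets for term over-representation against
   every catalog (one-sided hypergeometric upper tail against the
   catalog's own gene universe, Benjamini–Hochberg adjusted per
   catalog, significant at adjusted p < 0.05);
5. partitions significant terms into Venn regions per catalog and, for
   terms significant in *every* chemical, computes the product-form
   joint p-value (tracked in log10 space so products like 1E-68 keep an
   exact magnitude);
6. runs the same enrichment on the union of all target sets — the
   mixture treated as a single exposure.

A seeded synthetic-data generator (`chemmix.fixtures`) produces complete,
internally consistent bundles with planted shared targets and planted
co-enriched terms, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic bundle with planted signals
chemmix fixture --out fx/ --seed 42

# analyze a mixture (works identically on real STITCH-style dumps)
chemmix analyze \
    --chemicals chem1,chem2 \
    --level high \
    --links fx/links.tsv \
    --aliases fx/aliases.tsv \
    --map fx/protein_genes.tsv \
    --gmt GO=fx/go.gmt --gmt KEGG=fx/kegg.gmt --gmt DO=fx/do.gmt \
    --out results/

# verify planted signals survive the full pipeline
chemmix selfcheck --seed 42
```

`analyze` writes per-chemical target and enrichment CSVs,
`venn_regions.json`, per-catalog `shared_terms_*.csv` (per-chemical
adjusted p columns plus the formatted joint p-value and its
full-precision companions) and `overall_enrichment_*.csv`; add
`--formats csv,json,xlsx` for a single workbook mirroring the CSVs.
`--threshold INT` overrides `--level`; `--alpha FLOAT` changes the
significance cutoff. Exit codes: 0 success, 2 contract error (e.g. more
than four chemicals), 3 unresolvable chemical, 4 file-format error.

## Library

```python
import chemmix as cm

bundle = cm.DataBundle.load("links.tsv", "aliases.tsv", "map.tsv", {"DO": "do.gmt"})
report = cm.analyze_mixture(["chem1", "chem2"], bundle, level="high")
report.target_venn.full_intersection      # genes shared by all chemicals
report.shared_terms["DO"]                 # joint p-values, ascending
cm.write_report(report, "out/")
```

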