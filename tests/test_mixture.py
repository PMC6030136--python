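import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemmix import (
    AnnotationCatalog,
    ChemicalNotFoundError,
    ContractError,
    DomainError,
    EnrichmentRecord,
    EnrichmentTable,
    InteractionRecord,
    InteractionTable,
    ProteinGeneMap,
    analyze_mixture,
    enrich,
    joint_pvalue,
    overall_enrichment,
    select_targets,
    shared_term_analysis,
    venn_partition,
)
from chemmix.io import GeneInfo
from chemmix.mixture import CONFIDENCE_LEVELS, ConfidenceLevel, get_confidence_level


def make_map(pairs):
    return ProteinGeneMap(
        entries={p: GeneInfo(g, str(i), f"{g} protein") for i, (p, g) in enumerate(pairs)}
    )


class TestConfidenceLevels:
    def test_ordering(self):
        assert (
            CONFIDENCE_LEVELS["low"].min_score
            < CONFIDENCE_LEVELS["medium"].min_score
            < CONFIDENCE_LEVELS["high"].min_score
        )

    def test_stitch_convention(self):
        assert CONFIDENCE_LEVELS["low"].min_score == 150
        assert CONFIDENCE_LEVELS["medium"].min_score == 400
        assert CONFIDENCE_LEVELS["high"].min_score == 700

    def test_integer_threshold(self):
        assert get_confidence_level(333).min_score == 333

    def test_unknown_name(self):
        with pytest.raises(ContractError):
            get_confidence_level("extreme")


class TestSelectTargets:
    def table(self):
        return InteractionTable.from_records(
            [
                InteractionRecord("C1", "P1", 200),
                InteractionRecord("C1", "P2", 450),
                InteractionRecord("C1", "P3", 900),
            ]
        )

    def test_medium_threshold_keeps_two(self):
        ts = select_targets(
            self.table(), "C1", CONFIDENCE_LEVELS["medium"],
            make_map([("P1", "A"), ("P2", "B"), ("P3", "C")]),
        )
        assert ts.genes == {"B", "C"}

    def test_zero_threshold_keeps_all_mapped(self):
        ts = select_targets(
            self.table(), "C1", ConfidenceLevel("all", 0),
            make_map([("P1", "A"), ("P2", "B"), ("P3", "C")]),
        )
        assert ts.genes == {"A", "B", "C"}

    def test_gene_score_max_collapse(self):
        table = InteractionTable.from_records(
            [InteractionRecord("C1", "P1", 500), InteractionRecord("C1", "P2", 800)]
        )
        ts = select_targets(
            table, "C1", ConfidenceLevel("all", 0),
            make_map([("P1", "A"), ("P2", "A")]),
        )
        assert ts.per_gene_score == {"A": 800}

    def test_unmapped_proteins_excluded(self):
        ts = select_targets(
            self.table(), "C1", ConfidenceLevel("all", 0), make_map([("P1", "A")])
        )
        assert ts.genes == {"A"}
        assert ts.unmapped_proteins == {"P2", "P3"}

    def test_absent_chemical_errors(self):
        with pytest.raises(ChemicalNotFoundError):
            select_targets(
                self.table(), "C9", CONFIDENCE_LEVELS["low"], make_map([])
            )

    def test_empty_after_filtering_is_not_an_error(self):
        ts = select_targets(
            self.table(), "C1", ConfidenceLevel("super", 950),
            make_map([("P1", "A"), ("P2", "B"), ("P3", "C")]),
        )
        assert ts.genes == set()


def brute_force_regions(labeled_sets):
    """Assign each element by checking membership in every set (oracle)."""
    labels = list(labeled_sets)
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = set()
    union = set().union(*labeled_sets.values())
    for x in union:
        key = frozenset(l for l in labels if x in labeled_sets[l])
        regions[key].add(x)
    return regions


class TestVennPartition:
    def test_two_sets_by_hand(self):
        venn = venn_partition({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert venn.region("A") == {"g1"}
        assert venn.region("B") == {"g3"}
        assert venn.region("A", "B") == {"g2"}

    def test_identical_three_sets(self):
        venn = venn_partition({"A": {"x"}, "B": {"x"}, "C": {"x"}})
        assert venn.region("A", "B", "C") == {"x"}
        empties = [k for k, v in venn.regions.items() if not v]
        assert len(empties) == 6

    def test_three_sets_derived(self):
        sets = {"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g2"}}
        venn = venn_partition(sets)
        assert venn.regions == brute_force_regions(sets)
        assert venn.region("A", "B", "C") == {"g2"}
        assert sum(1 for v in venn.regions.values() if not v) == 4

    @pytest.mark.parametrize("n", [0, 1, 5])
    def test_set_count_limits(self, n):
        with pytest.raises(ContractError):
            venn_partition({f"S{i}": {"x"} for i in range(n)})

    def test_all_regions_present(self):
        venn = venn_partition({"A": set(), "B": set(), "C": set(), "D": {"z"}})
        assert len(venn.regions) == 15

    @given(
        st.integers(min_value=2, max_value=4),
        st.data(),
    )
    def test_conservation_and_disjointness(self, n, data):
        elements = st.sampled_from([f"e{i}" for i in range(12)])
        sets = {
            f"S{i}": data.draw(st.sets(elements, max_size=12)) for i in range(n)
        }
        venn = venn_partition(sets)
        union = set().union(*sets.values())
        assert venn.union() == union
        assert sum(len(v) for v in venn.regions.values()) == len(union)
        assert venn.regions == brute_force_regions(sets)

    def test_label_permutation_equivariance(self):
        sets = {"A": {"1", "2"}, "B": {"2", "3"}, "C": {"3", "4"}}
        venn1 = venn_partition(sets)
        venn2 = venn_partition({k: sets[k] for k in ["C", "A", "B"]})
        assert venn1.regions == venn2.regions

    def test_json_keys_sorted_plus_joined(self):
        venn = venn_partition({"genistein": {"x"}, "daidzein": {"x"}})
        assert "daidzein+genistein" in venn.to_json_dict()


class TestJointPValue:
    def test_table_row_hepatitis(self):
        j = joint_pvalue({"rifampin": 4.32e-08, "efavirenz": 0.00906})
        assert f"{j.joint_p:.2E}" == "3.91E-10"

    def test_table_row_endocrine(self):
        j = joint_pvalue({"daidzein": 9.11e-12, "genistein": 5.51e-21})
        assert f"{j.joint_p:.2E}" == "5.02E-32"

    def test_single_chemical_identity(self):
        assert joint_pvalue({"c": 0.37}).joint_p == 0.37

    def test_three_chemicals_derived(self):
        j = joint_pvalue({"a": 0.01, "b": 0.02, "c": 0.05})
        assert j.joint_p == pytest.approx(1e-5, rel=1e-12)

    def test_log10_matches_product(self):
        j = joint_pvalue({"a": 1e-3, "b": 1e-4})
        assert j.log10_joint_p == pytest.approx(math.log10(j.joint_p), abs=1e-9)

    def test_underflow_keeps_exact_log10(self):
        j = joint_pvalue({"a": 1e-200, "b": 1e-200})
        assert j.joint_p == 0.0
        assert j.log10_joint_p == pytest.approx(-400.0)
        assert not j.has_zero_input

    def test_zero_input_flagged(self):
        j = joint_pvalue({"a": 0.0, "b": 0.5})
        assert j.joint_p == 0.0
        assert j.log10_joint_p == -math.inf
        assert j.has_zero_input

    def test_empty_mapping_errors(self):
        with pytest.raises(ContractError):
            joint_pvalue({})

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            joint_pvalue({"a": bad})

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.floats(min_value=1e-300, max_value=1.0),
            min_size=1,
            max_size=4,
        )
    )
    def test_joint_le_min_and_log_agreement(self, values):
        j = joint_pvalue(values)
        assert j.joint_p <= min(values.values()) * (1 + 1e-12)
        if j.joint_p > 1e-290:
            assert j.log10_joint_p == pytest.approx(
                math.log10(j.joint_p), rel=1e-9, abs=1e-9
            )


def table_from(label, namespace, entries, alpha=0.05):
    """entries: term_id -> p_adj; counts are placeholders."""
    records = [
        EnrichmentRecord(t, f"desc {t}", 1, 2, 3, 10, p, p, p < alpha)
        for t, p in entries.items()
    ]
    records.sort(key=lambda r: (r.p_adj, r.term_id))
    return EnrichmentTable(label=label, namespace=namespace, records=records)


class TestSharedTermAnalysis:
    def test_shared_term_gets_product(self):
        tables = {
            "c1": table_from("c1", "DO", {"T1": 0.01, "T2": 0.5}),
            "c2": table_from("c2", "DO", {"T1": 0.02, "T2": 0.01}),
        }
        venn, joints = shared_term_analysis(tables)
        assert venn.full_intersection == {"T1"}
        assert len(joints) == 1
        assert joints[0].term_id == "T1"
        assert joints[0].joint_p == pytest.approx(0.01 * 0.02)

    def test_exclusive_term_not_scored(self):
        tables = {
            "c1": table_from("c1", "DO", {"T1": 0.01}),
            "c2": table_from("c2", "DO", {"T1": 0.9}),
        }
        venn, joints = shared_term_analysis(tables)
        assert venn.region("c1") == {"T1"}
        assert joints == []

    def test_three_chemicals_derived(self):
        tables = {
            c: table_from(c, "DO", {"T": p}, alpha=0.051)
            for c, p in [("c1", 0.01), ("c2", 0.02), ("c3", 0.05)]
        }
        _, joints = shared_term_analysis(tables)
        assert joints[0].joint_p == pytest.approx(1e-5, rel=1e-12)

    def test_namespace_mismatch(self):
        tables = {
            "c1": table_from("c1", "DO", {"T": 0.01}),
            "c2": table_from("c2", "GO", {"T": 0.01}),
        }
        with pytest.raises(ContractError):
            shared_term_analysis(tables)

    def test_sorted_by_joint_ascending(self):
        tables = {
            "c1": table_from("c1", "DO", {"T1": 0.04, "T2": 0.001}),
            "c2": table_from("c2", "DO", {"T1": 0.04, "T2": 0.001}),
        }
        _, joints = shared_term_analysis(tables)
        assert [j.term_id for j in joints] == ["T2", "T1"]

    def test_chemical_count_limits(self):
        with pytest.raises(ContractError):
            shared_term_analysis({"c1": table_from("c1", "DO", {"T": 0.01})})


def two_term_catalog():
    genes = [f"g{i}" for i in range(1, 11)]
    return AnnotationCatalog(
        namespace="GO",
        terms={
            "GO:A": ("a", frozenset(genes[:4])),
            "GO:B": ("b", frozenset(genes)),
        },
    )


class FakeTargets:
    def __init__(self, genes):
        self.genes = set(genes)


class TestOverallEnrichment:
    def test_single_set_equals_own_enrichment(self):
        catalog = two_term_catalog()
        single = overall_enrichment([FakeTargets({"g1", "g2"})], catalog)
        own = enrich({"g1", "g2"}, catalog, label="union")
        assert single.records == own.records

    def test_disjoint_sets_union(self):
        catalog = two_term_catalog()
        combined = overall_enrichment(
            [FakeTargets({"g1"}), FakeTargets({"g2"})], catalog
        )
        assert combined.records == enrich({"g1", "g2"}, catalog, label="union").records
        assert combined.label == "union"

    def test_duplicate_sets_idempotent(self):
        catalog = two_term_catalog()
        once = overall_enrichment([FakeTargets({"g1", "g3"})], catalog)
        twice = overall_enrichment(
            [FakeTargets({"g1", "g3"}), FakeTargets({"g1", "g3"})], catalog
        )
        assert once.records == twice.records

    def test_empty_input_errors(self):
        with pytest.raises(ContractError):
            overall_enrichment([], two_term_catalog())


class TestIntersectionMonotonicity:
    @given(
        st.lists(
            st.sets(st.sampled_from([f"t{i}" for i in range(8)]), max_size=8),
            min_size=3,
            max_size=4,
        )
    )
    def test_subset_intersection_is_superset(self, sig_sets):
        full = set.intersection(*sig_sets)
        partial = set.intersection(*sig_sets[:-1])
        assert partial >= full
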