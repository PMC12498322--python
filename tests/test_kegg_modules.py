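"""Module grammar parsing, completeness evaluation and annotation IO."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidcheck.kegg_modules import (
    CatalogError,
    KOProfile,
    Leaf,
    ModuleParseError,
    Node,
    coverage_vector,
    load_ko_annotations,
    module_completeness,
    parse_module_definition,
    write_ko_annotations,
)


def brute_force_step_satisfied(expr, present, optional):
    """Independent recursive evaluator used as the truth-table oracle."""
    if isinstance(expr, Leaf):
        return expr.ko in optional or expr.ko in present
    child_vals = [brute_force_step_satisfied(c, present, optional) for c in expr.children]
    if expr.kind == "any":
        return True in child_vals
    return False not in child_vals


def brute_force_completeness(definition, present):
    sat = [
        brute_force_step_satisfied(s, frozenset(present), definition.optional_leaves)
        for s in definition.steps
    ]
    return sum(sat) / len(sat)


class TestParser:
    @pytest.mark.parametrize(
        "definition,n_steps,canonical",
        [
            ("K00001 K00002", 2, "K00001 K00002"),
            ("(K00001,K00003) K00002", 2, "(K00001,K00003) K00002"),
            ("K00001+K00002", 1, "(K00001+K00002)"),
            ("K00001,K00002 K00003", 2, "(K00001,K00002) K00003"),
            ("(K00001 K00002) K00003", 2, "(K00001+K00002) K00003"),
            ("K00001-K00002", 1, "(K00001-K00002)"),
        ],
    )
    def test_step_counts_and_canonical_form(self, definition, n_steps, canonical):
        mod = parse_module_definition("M_t", definition)
        assert mod.n_steps == n_steps
        assert mod.canonical() == canonical

    def test_canonical_round_trip(self, catalog):
        for mod in catalog:
            re_parsed = parse_module_definition(mod.module_id, mod.canonical())
            assert re_parsed.canonical() == mod.canonical()
            assert re_parsed.n_steps == mod.n_steps
            assert re_parsed.optional_leaves == mod.optional_leaves

    def test_optional_leaves_recorded(self):
        mod = parse_module_definition("M_o", "K00001-K00002 K00003")
        assert mod.optional_leaves == {"K00002"}

    @pytest.mark.parametrize("bad", ["", "   ", "(K00001", "K00001)", "K1 K00002", "()"])
    def test_malformed_definitions_raise_with_position(self, bad):
        with pytest.raises(ModuleParseError):
            parse_module_definition("M_bad", bad)


class TestCompleteness:
    def test_empty_and_full_sets(self, toy_modules):
        m = toy_modules["and_of_steps"]
        assert module_completeness(m, set()) == 0.0
        assert module_completeness(m, {"K00001", "K00002"}) == 1.0
        assert module_completeness(m, {"K00001"}) == 0.5

    def test_or_alternative_satisfies_step(self, toy_modules):
        assert module_completeness(toy_modules["or_step"], {"K00003", "K00002"}) == 1.0

    def test_complex_requires_all_members(self, toy_modules):
        m = toy_modules["complex"]
        assert module_completeness(m, {"K00001"}) == 0.0
        assert module_completeness(m, {"K00001", "K00002"}) == 1.0

    def test_truth_table_oracle_equivalence(self, catalog):
        """Implementation agrees with the exhaustive brute-force oracle
        on every subset of every small bundled module's KO universe."""
        checked = 0
        for mod in catalog:
            kos = sorted(mod.kos)
            if len(kos) > 8:
                continue
            for r in range(len(kos) + 1):
                for subset in itertools.combinations(kos, r):
                    assert module_completeness(mod, set(subset)) == pytest.approx(
                        brute_force_completeness(mod, set(subset))
                    )
                    checked += 1
        assert checked > 500

    @given(a=st.sets(st.sampled_from([f"K{i:05d}" for i in range(1, 9)])),
           b=st.sets(st.sampled_from([f"K{i:05d}" for i in range(1, 9)])))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_ko_set(self, a, b, catalog):
        """Adding KOs never lowers any module's completeness."""
        sub, sup = a & b, a | b
        for mod in catalog[:5]:
            assert module_completeness(mod, sub) <= module_completeness(mod, sup)

    def test_optional_leaf_neutrality(self, catalog):
        for mod in catalog:
            if not mod.optional_leaves:
                continue
            full = set(mod.kos)
            assert module_completeness(mod, full) == module_completeness(
                mod, full - mod.optional_leaves
            )


class TestCoverageVector:
    def test_empty_and_full_profiles(self, catalog):
        all_kos = {k for m in catalog for k in m.kos}
        empty = coverage_vector(KOProfile("e", {}), catalog)
        assert set(empty.values) == {0.0}
        full = coverage_vector(KOProfile("f", {k: 1 for k in all_kos}), catalog)
        assert set(full.values) == {1.0}

    def test_per_module_values(self, toy_modules):
        cv = coverage_vector(
            KOProfile("g", {"K00001": 3}),
            [toy_modules["and_of_steps"], toy_modules["complex"]],
        )
        assert cv.values == (0.5, 0.0)
        assert cv.module_order == ("M_toy1", "M_toy3")

    def test_counts_beyond_one_do_not_matter(self, catalog):
        a = coverage_vector(KOProfile("a", {"K02703": 1, "K02704": 1}), catalog)
        b = coverage_vector(KOProfile("b", {"K02703": 9, "K02704": 4}), catalog)
        assert a.values == b.values

    def test_binary_mode(self, toy_modules):
        cv = coverage_vector(
            KOProfile("g", {"K00001": 1}), [toy_modules["and_of_steps"]], binary=True
        )
        assert cv.values == (0.0,)

    def test_duplicate_catalog_ids_rejected(self, toy_modules):
        m = toy_modules["and_of_steps"]
        with pytest.raises(CatalogError, match="duplicate"):
            coverage_vector(KOProfile("g", {}), [m, m])


class TestAnnotationIO:
    def test_aggregation_and_partitioning(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "genome_id\tgene_id\tko_id\n"
            "g1\tgene1\tK00001\n"
            "g1\tgene2\tK00001\n"
            "g1\tgene3\t\n"
            "g2\tgene1\tK00002\n"
        )
        profiles = {p.genome_id: p for p in load_ko_annotations(path)}
        assert profiles["g1"].counts == {"K00001": 2}
        assert profiles["g2"].counts == {"K00002": 1}

    def test_all_unannotated_gives_empty_profile(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("genome_id\tgene_id\tko_id\ng1\tgene1\t\n")
        (p,) = load_ko_annotations(path)
        assert p.total == 0 and p.counts == {}

    def test_missing_columns_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome\tko\na\tb\n")
        with pytest.raises(ValueError, match="genome_id"):
            load_ko_annotations(path)

    def test_round_trip(self, tmp_path, small_profile):
        path = tmp_path / "rt.tsv"
        write_ko_annotations([small_profile], path)
        (back,) = load_ko_annotations(path)
        assert back.counts == small_profile.counts

    def test_row_order_invariance(self, tmp_path, catalog):
        rows = [f"g1\tgene{i}\tK0270{3+i%4}" for i in range(8)]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        header = "genome_id\tgene_id\tko_id\n"
        a.write_text(header + "\n".join(rows) + "\n")
        b.write_text(header + "\n".join(reversed(rows)) + "\n")
        va = coverage_vector(load_ko_annotations(a)[0], catalog)
        vb = coverage_vector(load_ko_annotations(b)[0], catalog)
        assert va.values == vb.values
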