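"""Statement parsing, normalization, unification, serialization, rendering."""

import random

import pytest

from belhier.bel_core import (
    BELNode,
    BELTree,
    apply_placeholders,
    build_placeholder_map,
    canonicalize_statement_text,
    dedupe_trees,
    deserialize_sequence,
    normalize_statement,
    parse_statement,
    render_statement,
    serialize_tree,
    split_unified,
    unify_trees,
)
from belhier.errors import (
    BELParseError,
    MalformedSequenceError,
    RenderError,
    UnsupportedRelationError,
)
from belhier.synth_fixtures import random_tree


class TestParse:
    def test_hierarchical_statement_structure(self):
        tree = parse_statement(
            "cat(p(HGNC:IL2)) increases complex(p(HGNC:LYN), p(HGNC:IL2RB))"
        )
        root = tree.root
        assert root.kind == "relation" and root.label == "increases"
        cat, cplx = root.children
        assert cat.kind == "function" and cat.label == "cat"
        assert cat.children[0] == BELNode("entity", "HGNC:IL2", entity_type="gene")
        assert cplx.label == "complex"
        assert [c.label for c in cplx.children] == ["HGNC:LYN", "HGNC:IL2RB"]

    def test_minimal_two_entity_statement(self):
        tree = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        assert tree.root.label == "increases"
        assert all(c.kind == "entity" for c in tree.root.children)

    def test_quoted_identifiers(self):
        tree = parse_statement('p(HGNC:BMP2) decreases bp(GOBP:"cell cycle")')
        assert tree.root.children[1].label == "GOBP:cell cycle"
        assert tree.root.children[1].entity_type == "bp"

    @pytest.mark.parametrize(
        "text",
        ["p(HGNC:A increases p(HGNC:B)", "p(HGNC:A)) increases p(HGNC:B)"],
    )
    def test_unbalanced_parentheses_name_offset(self, text):
        with pytest.raises(BELParseError) as exc:
            parse_statement(text)
        assert "offset" in str(exc.value)

    def test_unknown_relation_keyword(self):
        with pytest.raises(UnsupportedRelationError):
            parse_statement("p(HGNC:A) correlates p(HGNC:B)")

    @pytest.mark.parametrize(
        "text",
        [
            "p(HGNC:A) increases (p(HGNC:B) decreases p(HGNC:C))",
            "p(HGNC:A) increases increases(p(HGNC:B), p(HGNC:C))",
        ],
    )
    def test_nested_relation_rejected(self, text):
        with pytest.raises((UnsupportedRelationError, BELParseError)):
            parse_statement(text)


class TestNormalize:
    def test_pmod_elevated_above_entity(self):
        tree = parse_statement("p(HGNC:AKT1, pmod(P, S, 21)) increases p(HGNC:B)")
        norm = normalize_statement(tree)
        pmod = norm.root.children[0]
        assert pmod.kind == "function" and pmod.label == "pmod"
        assert pmod.children[0] == BELNode("entity", "HGNC:AKT1", entity_type="gene")
        assert [c.label for c in pmod.children[1:]] == ["P", "S", "21"]

    def test_identity_without_modifications(self):
        tree = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        assert normalize_statement(tree) == tree

    def test_idempotent_and_entity_preserving_on_random_trees(self):
        rng = random.Random(42)
        for _ in range(1000):
            tree = random_tree(rng)
            once = normalize_statement(tree)
            assert normalize_statement(once) == once
            assert sorted(n.label for n in once.entity_leaves()) == sorted(
                n.label for n in tree.entity_leaves()
            )

    def test_dedupe_identical_statements(self):
        a = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        b = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        c = parse_statement("p(HGNC:A) decreases p(HGNC:B)")
        assert dedupe_trees([a, b, c]) == [a, c]


class TestUnify:
    def test_singleton_passthrough(self):
        t = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        assert unify_trees([t]) is t

    def test_two_trees_under_or_root(self):
        t1 = parse_statement("p(HGNC:BMP2) decreases bp(GOBP:apoptosis)")
        t2 = parse_statement("p(HGNC:BMP2) decreases p(HGNC:TP53)")
        unified = unify_trees([t1, t2])
        assert unified.root.kind == "or"
        assert unified.root.children == [t1.root, t2.root]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            unify_trees([])

    def test_split_is_inverse_of_unify(self):
        rng = random.Random(7)
        for _ in range(200):
            trees = [random_tree(rng) for _ in range(rng.randint(1, 4))]
            roundtrip = split_unified(unify_trees(list(trees)))
            assert roundtrip == trees

    def test_split_plain_tree_is_singleton(self):
        t = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        assert split_unified(t) == [t]


class TestSerialization:
    def test_castanospermine_node_sequence(self):
        tree = parse_statement(
            "a(CHEBI:castanospermine) decreases complex(p(MGI:Asgr2), p(MGI:Pdia3))"
        )
        seq = serialize_tree(tree, build_placeholder_map(tree))
        assert seq == ["decreases@2", "CHEM_1", "complex@2", "GENE_1", "GENE_2"]

    def test_flat_relation(self):
        tree = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        assert serialize_tree(tree, build_placeholder_map(tree)) == [
            "increases@2", "GENE_1", "GENE_2",
        ]

    def test_missing_placeholder_names_entity(self):
        tree = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        with pytest.raises(KeyError, match="HGNC:A"):
            serialize_tree(tree, {})

    def test_deserialize_recovers_shape(self):
        tree = deserialize_sequence(
            ["decreases@2", "CHEM_1", "complex@2", "GENE_1", "GENE_2"]
        )
        assert tree.root.label == "decreases"
        cplx = tree.root.children[1]
        assert cplx.label == "complex"
        assert [c.label for c in cplx.children] == ["GENE_1", "GENE_2"]

    @pytest.mark.parametrize(
        "seq",
        [
            ["increases@2", "GENE_1"],  # underflow
            ["increases@2", "GENE_1", "GENE_2", "GENE_3"],  # overflow
            [],
        ],
    )
    def test_malformed_sequences_rejected(self, seq):
        with pytest.raises(MalformedSequenceError):
            deserialize_sequence(seq)

    def test_roundtrip_on_random_trees(self):
        rng = random.Random(99)
        for _ in range(1000):
            tree = random_tree(rng)
            pmap = build_placeholder_map(tree)
            anonymized = apply_placeholders(tree, pmap)
            seq = serialize_tree(tree, pmap)
            assert deserialize_sequence(seq) == anonymized
            assert serialize_tree(deserialize_sequence(seq)) == seq

    def test_exactly_one_root_token(self):
        # total arity consumes every token but the root
        rng = random.Random(5)
        for _ in range(300):
            tree = random_tree(rng)
            seq = serialize_tree(tree, build_placeholder_map(tree))
            arity_sum = sum(
                int(tok.rsplit("@", 1)[1]) for tok in seq if "@" in tok
            )
            assert arity_sum == len(seq) - 1


class TestRender:
    def test_pmod_pushed_back_inside_entity(self):
        tree = normalize_statement(
            parse_statement("p(HGNC:AKT1, pmod(P, S, 21)) increases p(HGNC:B)")
        )
        rendered = render_statement(tree)
        assert canonicalize_statement_text(rendered) == (
            "p(HGNC:AKT1,pmod(P,S,21)) increases p(HGNC:B)"
        )

    def test_flat_statement(self):
        tree = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        assert render_statement(tree) == "p(HGNC:A) increases p(HGNC:B)"

    def test_or_root_rejected(self):
        t1 = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        with pytest.raises(RenderError):
            render_statement(unify_trees([t1, t1.copy()]))

    def test_unresolvable_placeholder_rejected(self):
        tree = deserialize_sequence(["increases@2", "GENE_1", "GENE_2"])
        with pytest.raises(RenderError):
            render_statement(tree)

    def test_placeholders_resolved_via_entity_table(self):
        tree = deserialize_sequence(["increases@2", "GENE_1", "CHEM_1"])
        table = {"GENE_1": ("HGNC", "AKT1", "gene"), "CHEM_1": ("CHEBI", "x y", "chem")}
        assert render_statement(tree, table) == 'p(HGNC:AKT1) increases a(CHEBI:"x y")'

    def test_parse_render_roundtrip_on_random_trees(self):
        rng = random.Random(2024)
        for _ in range(1000):
            tree = random_tree(rng)
            reparsed = normalize_statement(parse_statement(render_statement(tree)))
            assert reparsed == tree
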