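"""Layer assignment, tag generation from alignments, tree reconstruction."""

import pytest

from belhier.bel_core import deserialize_sequence, parse_statement
from belhier.errors import TagGenerationError
from belhier.hier_tagging import (
    LayeredTags,
    assign_layers,
    generate_tags,
    read_tag_file,
    repair_bieso,
    spans_of,
    tags_to_tree,
    write_tag_file,
)
from belhier.parallel_align import Alignment
from belhier.synth_fixtures import GenConfig, generate_corpus, random_tree

FIG_TOKENS = "Preincubation with CHEM_1 prevented association of GENE_1 to GENE_2".split()
FIG_TREE = deserialize_sequence(["decreases@2", "CHEM_1", "complex@2", "GENE_1", "GENE_2"])
FIG_LINKS = [(2, 1), (3, 0), (4, 2), (6, 3), (8, 4)]


class TestAssignLayers:
    def test_flat_relation_two_layers(self):
        tree = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        layers = assign_layers(tree)
        assert layers.L == 2
        assert layers[tree.root] == 2
        assert all(layers[c] == 1 for c in tree.root.children)

    def test_function_statement_three_layers(self):
        tree = parse_statement(
            "cat(p(HGNC:IL2)) increases complex(p(HGNC:LYN), p(HGNC:IL2RB))"
        )
        layers = assign_layers(tree)
        assert layers.L == 3
        cat, cplx = tree.root.children
        assert layers[cat] == 2 and layers[cplx] == 2
        assert layers[tree.root] == 3

    def test_parent_above_children_on_random_trees(self, rng):
        for _ in range(300):
            tree = random_tree(rng)
            layers = assign_layers(tree)
            for node in tree.root.preorder():
                for child in node.children:
                    assert layers[node] > layers[child]


class TestGenerateTags:
    def test_published_pair_layered_tags(self):
        tags = generate_tags(FIG_TOKENS, FIG_TREE, Alignment(links=FIG_LINKS))
        assert tags.layers[0] == [
            "O", "O", "S-CHEM", "O", "O", "O", "S-GENE", "O", "S-GENE",
        ]
        # complex span runs from its trigger word through its last entity
        assert tags.layers[1] == [
            "O", "O", "O", "O", "B-complex", "I-complex", "I-complex",
            "I-complex", "E-complex",
        ]
        # decreases span covers its trigger plus all descendants
        assert tags.layers[2] == [
            "O", "O", "B-decreases", "I-decreases", "I-decreases", "I-decreases",
            "I-decreases", "I-decreases", "E-decreases",
        ]

    def test_adjacent_flat_relation(self):
        tree = deserialize_sequence(["increases@2", "GENE_1", "GENE_2"])
        tags = generate_tags(
            ["GENE_1", "elevated", "GENE_2"], tree,
            Alignment(links=[(0, 1), (1, 0), (2, 2)]),
        )
        assert tags.layers[0] == ["S-GENE", "O", "S-GENE"]
        assert tags.layers[1] == ["B-increases", "I-increases", "E-increases"]

    def test_unaligned_node_rejects_instance(self):
        tree = deserialize_sequence(["increases@2", "GENE_1", "GENE_2"])
        with pytest.raises(TagGenerationError):
            generate_tags(["GENE_1", "elevated", "GENE_2"], tree,
                          Alignment(links=[(0, 1), (1, 0)]))

    def test_overlapping_same_layer_spans_reject(self):
        # two relations forced onto interleaved spans cannot be tagged
        tree = deserialize_sequence(
            ["or@2", "increases@2", "GENE_1", "GENE_2",
             "decreases@2", "GENE_3", "GENE_4"]
        )
        links = [(0, 2), (1, 5), (2, 3), (3, 6), (4, 1), (5, 4)]
        with pytest.raises(TagGenerationError):
            generate_tags(["GENE_1", "GENE_3", "GENE_2", "GENE_4", "up", "down"],
                          tree, Alignment(links=links))

    def test_parameter_classes(self):
        tree = parse_statement(
            "pmod(p(HGNC:AKT1), P, S, 21) increases p(HGNC:B)"
        )
        tokens = ["GENE_1", "P", "S", "21", "elevated", "GENE_2"]
        # preorder: increases pmod GENE P S 21 GENE
        links = [(0, 2), (1, 3), (2, 4), (3, 5), (4, 0), (5, 6)]
        from belhier.bel_core import apply_placeholders, build_placeholder_map

        ptree = apply_placeholders(tree, build_placeholder_map(tree))
        tags = generate_tags(tokens, ptree, Alignment(links=links))
        assert tags.layers[0] == ["S-GENE", "S-P", "S-AA", "S-NUM", "O", "S-GENE"]


class TestTagsToTree:
    def test_published_pair_reconstruction(self):
        tags = generate_tags(FIG_TOKENS, FIG_TREE, Alignment(links=FIG_LINKS))
        assert tags_to_tree(tags, FIG_TOKENS) == FIG_TREE

    def test_all_o_yields_no_statement(self):
        tags = LayeredTags([["O", "O"], ["O", "O"]])
        assert tags_to_tree(tags, ["a", "b"]) is None

    def test_orphan_span_dropped(self):
        tags = LayeredTags([
            ["S-GENE", "O", "S-GENE", "O", "S-CHEM"],
            ["O", "O", "O", "O", "O"],
            ["B-increases", "I-increases", "E-increases", "O", "O"],
        ])
        tree = tags_to_tree(tags, ["GENE_1", "up", "GENE_2", "x", "CHEM_1"])
        # CHEM_1 sits outside the relation span and is dropped
        labels = [n.label for n in tree.root.preorder()]
        assert "CHEM_1" not in labels and labels[0] == "increases"

    def test_inverse_of_generation_on_synthetic_gold(self):
        corpus = generate_corpus(GenConfig(n_pairs=2000, seed=29))
        for pair in corpus:
            rebuilt = tags_to_tree(pair.gold_tags, pair.simplified_tokens)
            assert rebuilt == pair.unified

    def test_same_layer_spans_disjoint_in_gold(self, small_corpus):
        for pair in small_corpus:
            for layer in pair.gold_tags.layers:
                spans = spans_of(layer)
                for a, b in zip(spans, spans[1:]):
                    assert a[1] < b[0]


class TestRepair:
    def test_orphan_inside_opens_block(self):
        assert repair_bieso(["I-x", "I-x", "O"]) == ["B-x", "E-x", "O"]

    def test_unterminated_block_closed(self):
        assert repair_bieso(["B-x", "I-x"]) == ["B-x", "E-x"]
        assert repair_bieso(["B-x", "O"]) == ["S-x", "O"]

    def test_label_switch_starts_new_block(self):
        assert repair_bieso(["B-x", "I-y", "E-y"]) == ["S-x", "B-y", "E-y"]

    def test_wellformed_untouched(self):
        tags = ["B-x", "I-x", "E-x", "O", "S-y"]
        assert repair_bieso(tags) == tags


class TestTagFileIO:
    def test_roundtrip(self, tmp_path, small_corpus):
        instances = [(p.simplified_tokens, p.gold_tags) for p in small_corpus[:25]]
        path = tmp_path / "tags.conll"
        write_tag_file(instances, path)
        back = read_tag_file(path)
        assert len(back) == len(instances)
        for (tok_a, tags_a), (tok_b, tags_b) in zip(back, instances):
            assert tok_a == [t.surface for t in tok_b]
            assert tags_a.layers == tags_b.layers
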