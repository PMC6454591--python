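"""Pair filtering, pseudo-pair augmentation, EM aligner, link extraction."""

import random
from collections import defaultdict

import pytest

from belhier.entity_grounding import GroundingResult
from belhier.parallel_align import (
    Alignment,
    NULL_TOKEN,
    ParallelPair,
    alignment_error_rate,
    augment_pseudo_pairs,
    extract_alignment,
    filter_pairs,
    format_pharaoh,
    parse_pharaoh,
    placeholder_vocabulary,
    train_aligner,
)
from belhier.synth_fixtures import GenConfig, generate_corpus


def _pair(pid, src, tgt):
    return ParallelPair(pid, src.split(), tgt.split())


class TestFilterPairs:
    def test_fully_grounded_retained(self):
        items = [(_pair("a", "x", "y"), [GroundingResult("HGNC:A", (0, 1), "ner", 0.0)])]
        kept, dropped = filter_pairs(items)
        assert len(kept) == 1 and not dropped

    def test_absent_entity_drops_pair_with_reason(self):
        items = [(_pair("a", "x", "y"), [GroundingResult("HGNC:A", None, None)])]
        kept, dropped = filter_pairs(items)
        assert not kept
        assert dropped[0][0] == "a" and "HGNC:A" in dropped[0][1]

    def test_retained_count_matches_counting_oracle(self, rng):
        items = []
        expected = 0
        for i in range(100):
            n_ent = rng.randint(1, 4)
            absent_flags = [rng.random() < 0.3 for _ in range(n_ent)]
            grounding = [
                GroundingResult(f"HGNC:E{j}", None if absent else (j, j + 1),
                                None if absent else "dictionary",
                                None if absent else 0.0)
                for j, absent in enumerate(absent_flags)
            ]
            expected += not any(absent_flags)
            items.append((_pair(f"p{i:03d}", "w", "n"), grounding))
        kept, _ = filter_pairs(items)
        assert len(kept) == expected


class TestAugment:
    def test_zero_copies_is_identity(self):
        pairs = [_pair("a", "GENE_1 binds GENE_2", "increases@2 GENE_1 GENE_2")]
        assert augment_pseudo_pairs(pairs, copies=0) == pairs

    def test_growth_arithmetic(self):
        pairs = [_pair("a", "GENE_1 binds GENE_2", "increases@2 GENE_1 GENE_2")]
        vocab = placeholder_vocabulary(pairs)
        out = augment_pseudo_pairs(pairs, copies=7)
        assert len(out) == len(pairs) + 7 * len(vocab)
        assert all(p.source == p.target for p in out[len(pairs):])


# -- independent oracle: dictionary-based EM over the same model ------------


def _oracle_em(pairs, iterations):
    """Plain nested-loop Model 1 EM with a NULL token, weight 1."""
    cooc = defaultdict(set)
    for src, tgt in pairs:
        for node in tgt + [NULL_TOKEN]:
            cooc[node].update(src)
    t = {node: {w: 1.0 / len(ws) for w in ws} for node, ws in cooc.items()}
    for _ in range(iterations):
        counts = defaultdict(lambda: defaultdict(float))
        for src, tgt in pairs:
            nodes = tgt + [NULL_TOKEN]
            for w in src:
                z = sum(t[n].get(w, 0.0) for n in nodes)
                for n in nodes:
                    counts[n][w] += t[n].get(w, 0.0) / z
        t = {
            n: {w: c / sum(ws.values()) for w, c in ws.items()}
            for n, ws in counts.items()
        }
    return t


class TestTrainAligner:
    def test_degenerate_fixed_point(self):
        pairs = [_pair(f"p{i}", "x", "x") for i in range(5)]
        table = train_aligner(pairs, iterations=3)
        # x splits between the x node and NULL, but the x row is pure
        assert table.probs["x"]["x"] == pytest.approx(1.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_aligner([], iterations=1)

    def test_matches_hand_run_em_on_toy_corpus(self):
        # classic two-pair corpus with a shared word
        raw = [(["the", "house"], ["das", "Haus"]),
               (["the", "book"], ["das", "Buch"])]
        pairs = [ParallelPair(f"p{i}", s, t) for i, (s, t) in enumerate(raw)]
        table = train_aligner(pairs, iterations=2, null_weight=1.0)
        oracle = _oracle_em([(s, t) for s, t in raw], iterations=2)
        for node, row in oracle.items():
            for word, p in row.items():
                assert table.probs[node][word] == pytest.approx(p, abs=1e-9)

    def test_rows_normalized_after_every_iteration(self):
        corpus = generate_corpus(GenConfig(n_pairs=40, seed=9))
        pairs = [p.parallel_pair() for p in corpus]
        for iters in (1, 2, 5):
            table = train_aligner(pairs, iterations=iters)
            for row in table.probs.values():
                assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)

    def test_loglik_nondecreasing(self):
        corpus = generate_corpus(GenConfig(n_pairs=60, seed=13))
        table = train_aligner([p.parallel_pair() for p in corpus], iterations=8)
        history = table.loglik_history
        assert all(b >= a - 1e-9 for a, b in zip(history, history[1:]))

    def test_retraining_is_bit_identical(self):
        corpus = generate_corpus(GenConfig(n_pairs=50, seed=21))
        pairs = [p.parallel_pair() for p in corpus]
        t1 = train_aligner(augment_pseudo_pairs(pairs, 10), iterations=5)
        t2 = train_aligner(augment_pseudo_pairs(pairs, 10), iterations=5)
        assert t1.probs == t2.probs


class TestExtractAlignment:
    def test_single_identity_pair(self):
        pairs = [_pair(f"p{i}", "GENE_1", "GENE_1") for i in range(3)]
        table = train_aligner(pairs, iterations=2)
        assert extract_alignment(pairs[0], table).links == [(0, 0)]

    def test_published_alignment_example(self):
        """Trigger/function words align to their nodes; prepositions stay
        unaligned, reproducing the printed word/node link example."""
        corpus = generate_corpus(GenConfig.low_noise(n_pairs=500, seed=11))
        example = _pair(
            "zz-example",
            "Preincubation with CHEM_1 prevented association of GENE_1 to GENE_2",
            "decreases@2 CHEM_1 complex@2 GENE_1 GENE_2",
        )
        pairs = [p.parallel_pair() for p in corpus] + [example]
        table = train_aligner(augment_pseudo_pairs(pairs, copies=50), iterations=10)
        links = sorted(extract_alignment(example, table).links)
        assert links == [(2, 1), (3, 0), (4, 2), (6, 3), (8, 4)]

    def test_placeholder_links_forced_and_exact(self, low_noise_corpus):
        pairs = [p.parallel_pair() for p in low_noise_corpus[:200]]
        table = train_aligner(augment_pseudo_pairs(pairs, copies=50), iterations=10)
        for synth, pair in zip(low_noise_corpus[:200], pairs):
            alignment = extract_alignment(pair, table)
            gold = set(synth.gold_alignment.links)
            for i, j in alignment.links:
                if pair.source[i].split("_")[0] in ("GENE", "CHEM", "BP", "DIS"):
                    assert (i, j) in gold

    def test_repeated_placeholders_match_by_occurrence(self):
        pair = _pair("p", "GENE_1 binds GENE_1", "increases@2 GENE_1 GENE_1")
        table = train_aligner([pair], iterations=2)
        links = extract_alignment(pair, table).links
        assert (0, 1) in links and (2, 2) in links


class TestAerAndPharaoh:
    def test_aer_bounds(self):
        assert alignment_error_rate([(0, 0)], [(0, 0)]) == 0.0
        assert alignment_error_rate([(0, 1)], [(0, 0)]) == 1.0
        assert alignment_error_rate([], []) == 0.0

    def test_pharaoh_roundtrip(self):
        alignment = Alignment(links=[(0, 2), (3, 1), (5, 5)])
        assert parse_pharaoh(format_pharaoh(alignment)).links == sorted(alignment.links)
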