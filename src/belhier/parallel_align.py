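"""Parallel corpus construction and statistical word alignment.

The simplified sentence is the source language and the serialized BEL node
sequence the target language.  Alignment uses an IBM-Model-1-style lexical
translation model with a NULL node: EM learns t(word | node), the
probability that a target node emits a given source word, so several words
may align to one node but a word aligns to at most one node.  Pseudo-parallel
single-token pairs ("GENE_1" -> "GENE_1") bias entity placeholders toward
identity links; extraction additionally forces placeholder links outright.

Training is fully deterministic: pairs are iterated in pair_id order and all
tie-breaks are leftmost.  The ``seed`` argument is stored for provenance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from .bel_core import PLACEHOLDER_RE

NULL_TOKEN = "<NULL>"


@dataclass
class ParallelPair:
    pair_id: str
    source: list[str]  # simplified sentence words
    target: list[str]  # serialized node sequence
    gold_alignment: list[tuple[int, int]] | None = None


@dataclass
class Alignment:
    """Word->node links as (source index, target index); unlinked implicit."""

    links: list[tuple[int, int]] = field(default_factory=list)

    def linked_sources(self) -> set[int]:
        return {i for i, _ in self.links}


@dataclass
class TranslationTable:
    """t(source word | target node); rows (per node) sum to 1."""

    probs: dict[str, dict[str, float]] = field(default_factory=dict)
    loglik_history: list[float] = field(default_factory=list)
    seed: int = 0
    null_weight: float = 1.0

    def prob(self, word: str, node: str) -> float:
        return self.probs.get(node, {}).get(word, 0.0)


def filter_pairs(items):
    """Keep pairs whose every statement entity was grounded in the sentence.

    ``items`` is a list of (ParallelPair, list[GroundingResult]).  Returns
    (kept pairs, [(pair_id, reason) for dropped pairs]).
    """
    kept, dropped = [], []
    for pair, groundings in items:
        missing = [g.entity_key for g in groundings if g.absent]
        if missing:
            dropped.append((pair.pair_id, f"entities not found in sentence: {missing}"))
        else:
            kept.append(pair)
    return kept, dropped


def placeholder_vocabulary(pairs: list[ParallelPair]) -> list[str]:
    vocab = set()
    for p in pairs:
        for tok in list(p.source) + list(p.target):
            if PLACEHOLDER_RE.match(tok):
                vocab.add(tok)
    return sorted(vocab)


def augment_pseudo_pairs(pairs: list[ParallelPair], copies: int = 50) -> list[ParallelPair]:
    """Append ``copies`` single-token identity pairs per placeholder."""
    out = list(pairs)
    for tok in placeholder_vocabulary(pairs):
        for k in range(copies):
            out.append(ParallelPair(f"pseudo-{tok}-{k:04d}", [tok], [tok]))
    return out


def train_aligner(
    pairs: list[ParallelPair],
    iterations: int = 10,
    seed: int = 0,
    null_weight: float = 2.0,
    smoothing: float = 0.0,
) -> TranslationTable:
    """EM for the lexical translation table (uniform init, NULL included).

    ``null_weight`` counts the NULL node as that many virtual tokens per
    sentence and ``smoothing`` adds add-n smoothing over the source
    vocabulary in the M-step — the standard correctives for Model 1's
    tendency to attach frequent function words to content nodes instead of
    leaving them unaligned.
    """
    if not pairs:
        raise ValueError("train_aligner requires a non-empty corpus")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pairs = sorted(pairs, key=lambda p: p.pair_id)

    # uniform initialization over words co-occurring with each node
    cooc: dict[str, set[str]] = defaultdict(set)
    vocab: set[str] = set()
    for p in pairs:
        nodes = list(p.target) + [NULL_TOKEN]
        vocab.update(p.source)
        for node in nodes:
            cooc[node].update(p.source)
    t: dict[str, dict[str, float]] = {
        node: {w: 1.0 / len(words) for w in sorted(words)}
        for node, words in cooc.items()
    }
    v = len(vocab)

    history: list[float] = []
    for _ in range(iterations):
        counts: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
        totals: dict[str, float] = defaultdict(float)
        loglik = 0.0
        for p in pairs:
            nodes = list(p.target) + [NULL_TOKEN]
            weights = [1.0] * len(p.target) + [null_weight]
            for word in p.source:
                scores = [w * t[node].get(word, 0.0)
                          for node, w in zip(nodes, weights)]
                z = sum(scores)
                if z <= 0.0:
                    continue
                loglik += math.log(z / (len(p.target) + null_weight))
                for node, s in zip(nodes, scores):
                    delta = s / z
                    counts[node][word] += delta
                    totals[node] += delta
        for node, words in counts.items():
            total = totals[node] + smoothing * v
            t[node] = {w: (c + smoothing) / total for w, c in words.items()}
        history.append(loglik)
    return TranslationTable(probs=t, loglik_history=history, seed=seed,
                            null_weight=null_weight)


def extract_alignment(pair: ParallelPair, table: TranslationTable) -> Alignment:
    """Argmax word->node links; placeholders forced to their identical node.

    A source word whose best candidate is NULL stays unaligned.  Repeated
    placeholders match by occurrence order.  Ties break leftmost.
    """
    links: list[tuple[int, int]] = []
    # occurrence-order matching for placeholders present on both sides
    target_occ: dict[str, list[int]] = defaultdict(list)
    for j, tok in enumerate(pair.target):
        if PLACEHOLDER_RE.match(tok):
            target_occ[tok].append(j)
    used: dict[str, int] = defaultdict(int)

    for i, word in enumerate(pair.source):
        if PLACEHOLDER_RE.match(word) and target_occ.get(word):
            occ = target_occ[word]
            j = occ[min(used[word], len(occ) - 1)]
            used[word] += 1
            links.append((i, j))
            continue
        best_j, best_p = None, table.null_weight * table.prob(word, NULL_TOKEN)
        for j, node in enumerate(pair.target):
            p = table.prob(word, node)
            if p > best_p:
                best_p, best_j = p, j
        if best_j is not None and best_p > 0.0:
            links.append((i, best_j))
    return Alignment(links=links)


def alignment_error_rate(
    predicted: list[tuple[int, int]], gold: list[tuple[int, int]]
) -> float:
    """AER with sure links only: 1 - 2|A∩S| / (|A| + |S|)."""
    a, s = set(predicted), set(gold)
    if not a and not s:
        return 0.0
    return 1.0 - 2.0 * len(a & s) / (len(a) + len(s))


# ---------------------------------------------------------------------------
# Pharaoh format and corpus files


def format_pharaoh(alignment: Alignment) -> str:
    return " ".join(f"{i}-{j}" for i, j in sorted(alignment.links))


def parse_pharaoh(text: str) -> Alignment:
    links = []
    for chunk in text.split():
        i, j = chunk.split("-")
        links.append((int(i), int(j)))
    return Alignment(links=links)


def write_parallel_corpus(pairs: list[ParallelPair], source_path, target_path) -> None:
    with open(source_path, "w", encoding="utf-8") as fs, \
            open(target_path, "w", encoding="utf-8") as ft:
        for p in pairs:
            fs.write(" ".join(p.source) + "\n")
            ft.write(" ".join(p.target) + "\n")


def read_parallel_corpus(source_path, target_path) -> list[ParallelPair]:
    with open(source_path, encoding="utf-8") as fs:
        sources = [line.split() for line in fs if line.strip()]
    with open(target_path, encoding="utf-8") as ft:
        targets = [line.split() for line in ft if line.strip()]
    if len(sources) != len(targets):
        raise ValueError("source and target corpora differ in length")
    return [
        ParallelPair(f"pair-{i:06d}", s, t)
        for i, (s, t) in enumerate(zip(sources, targets))
    ]
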