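"""End-to-end orchestration: corpus -> aligner -> tagged instances -> model.

Ties the stages together the way the extraction system runs them: build the
parallel corpus from simplified sentences and serialized node sequences,
augment with pseudo-parallel placeholder pairs, train the EM aligner,
extract word->node alignments, generate layered training tags (instances
that cannot be tagged are dropped), train the stacked labelers, and at test
time convert predicted tags back into rendered BEL statements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .bel_core import render_statement, split_unified
from .errors import RenderError, TagGenerationError
from .evaluation import ScoreReport, score_trees
from .hier_tagging import LayeredTags, generate_tags, tags_to_tree
from .parallel_align import (
    Alignment,
    TranslationTable,
    alignment_error_rate,
    augment_pseudo_pairs,
    extract_alignment,
    train_aligner,
)
from .sequence_labeler import HierModel, predict_hier, train_hier
from .synth_fixtures import SynthPair

logger = logging.getLogger(__name__)


@dataclass
class TrainingArtifacts:
    table: TranslationTable
    alignments: dict[str, Alignment]
    instances: list[tuple[list, LayeredTags]]
    rejected: list[tuple[str, str]]
    model: HierModel
    L: int


def build_training_artifacts(
    pairs: list[SynthPair],
    copies: int = 50,
    iterations: int = 10,
    c2: float = 1.0,
    max_iter: int = 100,
    seed: int = 0,
) -> TrainingArtifacts:
    parallel = [p.parallel_pair() for p in pairs]
    augmented = augment_pseudo_pairs(parallel, copies=copies)
    table = train_aligner(augmented, iterations=iterations, seed=seed)

    alignments: dict[str, Alignment] = {}
    instances: list[tuple[list, LayeredTags]] = []
    rejected: list[tuple[str, str]] = []
    for pair, ppair in zip(pairs, parallel):
        alignment = extract_alignment(ppair, table)
        alignments[pair.pair_id] = alignment
        try:
            tags = generate_tags(pair.simplified_tokens, pair.unified, alignment)
        except TagGenerationError as e:
            rejected.append((pair.pair_id, str(e)))
            continue
        instances.append((pair.simplified_tokens, tags))
    if rejected:
        logger.info("rejected %d/%d instances during tag generation",
                    len(rejected), len(pairs))

    L = max(tags.L for _, tags in instances)
    model = train_hier(instances, L=L, c2=c2, max_iter=max_iter, seed=seed)
    return TrainingArtifacts(table, alignments, instances, rejected, model, L)


def predict_statements(pair: SynthPair, model: HierModel) -> list[str]:
    """Predict rendered BEL statements for one pair's simplified sentence."""
    tags = predict_hier(pair.simplified_tokens, model)
    tree = tags_to_tree(tags, pair.simplified_tokens)
    if tree is None:
        return []
    statements = []
    for sub in split_unified(tree):
        if sub.root.kind != "relation":
            continue
        try:
            statements.append(render_statement(sub, pair.entity_table))
        except RenderError as e:
            logger.warning("dropping unrenderable prediction for %s: %s",
                           pair.pair_id, e)
    return statements


@dataclass
class ExperimentResult:
    report: ScoreReport
    tag_accuracy: list[float]  # per layer, fraction in [0, 1]
    aer: float
    placeholder_precision: float
    n_train: int
    n_test: int
    n_instances: int
    n_rejected: int
    artifacts: TrainingArtifacts = field(repr=False, default=None)


def _placeholder_precision(pairs, alignments) -> float:
    from .bel_core import PLACEHOLDER_RE

    correct = total = 0
    for pair in pairs:
        gold = set(pair.gold_alignment.links)
        sources = [t.surface for t in pair.simplified_tokens]
        for i, j in alignments[pair.pair_id].links:
            if PLACEHOLDER_RE.match(sources[i]):
                total += 1
                correct += (i, j) in gold
    return correct / total if total else 1.0


def run_experiment(
    train_pairs: list[SynthPair],
    test_pairs: list[SynthPair],
    copies: int = 50,
    iterations: int = 10,
    c2: float = 1.0,
    max_iter: int = 100,
    seed: int = 0,
) -> ExperimentResult:
    """Train on *train_pairs*, evaluate alignment, tagging and statements."""
    artifacts = build_training_artifacts(
        train_pairs, copies=copies, iterations=iterations, c2=c2,
        max_iter=max_iter, seed=seed,
    )

    # alignment quality on the training pairs (gold links are known)
    links_pred, links_gold = [], []
    for idx, pair in enumerate(train_pairs):
        links_pred.extend((idx, i, j) for i, j in artifacts.alignments[pair.pair_id].links)
        links_gold.extend((idx, i, j) for i, j in pair.gold_alignment.links)
    aer = alignment_error_rate(links_pred, links_gold)
    placeholder_precision = _placeholder_precision(train_pairs, artifacts.alignments)

    # held-out per-layer tag accuracy and statement scores
    L = artifacts.L
    correct = [0] * L
    total = [0] * L
    gold_statements: dict[str, list] = {}
    pred_statements: dict[str, list] = {}
    for pair in test_pairs:
        predicted = predict_hier(pair.simplified_tokens, artifacts.model)
        gold = pair.gold_tags.padded(L)
        for k in range(L):
            for gtag, ptag in zip(gold.layers[k], predicted.layers[k]):
                total[k] += 1
                correct[k] += gtag == ptag
        gold_statements[pair.pair_id] = [
            render_statement(t) for t in pair.statements
        ]
        pred_statements[pair.pair_id] = predict_statements(pair, artifacts.model)

    report = score_trees(gold_statements, pred_statements)
    tag_accuracy = [c / t if t else 0.0 for c, t in zip(correct, total)]
    return ExperimentResult(
        report=report,
        tag_accuracy=tag_accuracy,
        aer=aer,
        placeholder_precision=placeholder_precision,
        n_train=len(train_pairs),
        n_test=len(test_pairs),
        n_instances=len(artifacts.instances),
        n_rejected=len(artifacts.rejected),
        artifacts=artifacts,
    )
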