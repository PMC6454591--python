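"""Multi-level scoring of predicted vs gold BEL statements.

Six evaluation levels project each statement onto progressively stricter
units: Term (entity terms), Function-Secondary (function name after
activity mapping + argument entities), Function (function with its inner
term), Relation-Secondary (relation type + each single argument), Relation
(relation type + both ordered arguments) and Statement (the full normalized
statement).  Throughout, ``directlyIncreases`` ≡ ``increases`` and
``directlyDecreases`` ≡ ``decreases``, and specific activity functions
(``kin``, ``tscript``, ``cat`` ...) map to the general ``act()``.

Matching is per sentence and multiset-aware; precision, recall and F1 are
reported as percentages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .bel_core import (
    BELNode,
    BELTree,
    DIRECT_TO_BASE,
    normalize_statement,
    parse_statement,
)
from .errors import FormatError

LEVELS = (
    "term",
    "function_secondary",
    "function",
    "relation_secondary",
    "relation",
    "statement",
)

#: BEL 1.0 activity family collapsed to act() during evaluation
ACTIVITY_FUNCS = {"act", "cat", "kin", "tscript", "phos", "gtp", "pep", "ribo",
                  "tport", "chap"}


def _map_func(name: str) -> str:
    return "act" if name in ACTIVITY_FUNCS else name


def _collapse_rel(name: str) -> str:
    return DIRECT_TO_BASE.get(name, name)


def _node_key(node: BELNode) -> str:
    """Canonical string of a subtree under the evaluation equivalences."""
    if node.kind == "entity":
        from .bel_core import _entity_term  # canonical p(NS:id) rendering

        return _entity_term(node, None)
    if node.kind == "parameter":
        return node.label
    if node.kind == "function":
        args = ",".join(_node_key(c) for c in node.children)
        return f"{_map_func(node.label)}({args})"
    if node.kind == "relation":
        args = ",".join(_node_key(c) for c in node.children)
        return f"{_collapse_rel(node.label)}({args})"
    raise ValueError(f"cannot canonicalize node kind '{node.kind}'")


def _subtree_entities(node: BELNode) -> list[str]:
    return sorted(n.label for n in node.preorder() if n.kind == "entity")


def canonicalize(statement: BELTree, level: str) -> Counter:
    """Multiset of canonical keys of *statement* at *level*."""
    if level not in LEVELS:
        raise ValueError(f"unknown level '{level}'")
    tree = normalize_statement(statement)
    root = tree.root
    items: Counter = Counter()
    if level == "term":
        for leaf in tree.entity_leaves():
            items[_node_key(leaf)] += 1
    elif level == "function":
        for node in root.preorder():
            if node.kind == "function":
                items[_node_key(node)] += 1
    elif level == "function_secondary":
        for node in root.preorder():
            if node.kind == "function":
                ents = "+".join(_subtree_entities(node))
                items[f"{_map_func(node.label)}|{ents}"] += 1
    elif level == "relation_secondary":
        for node in root.preorder():
            if node.kind == "relation":
                rel = _collapse_rel(node.label)
                for child in node.children:
                    items[f"{rel}|{_node_key(child)}"] += 1
    elif level == "relation":
        for node in root.preorder():
            if node.kind == "relation":
                rel = _collapse_rel(node.label)
                args = "|".join(_node_key(c) for c in node.children)
                items[f"{rel}|{args}"] += 1
    else:  # statement
        if root.kind == "or":
            for child in root.children:
                items[_node_key(child)] += 1
        else:
            items[_node_key(root)] += 1
    return items


@dataclass
class LevelScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class ScoreReport:
    levels: dict[str, LevelScore]

    def to_text(self) -> str:
        header = f"{'Evaluation Level':<20}{'P(%)':>8}{'R(%)':>8}{'F1(%)':>8}"
        rows = [header]
        pretty = {
            "term": "Term",
            "function_secondary": "Function-Secondary",
            "function": "Function",
            "relation_secondary": "Relation-Secondary",
            "relation": "Relation",
            "statement": "Statement",
        }
        for level in LEVELS:
            s = self.levels[level]
            rows.append(
                f"{pretty[level]:<20}{s.precision:>8.1f}{s.recall:>8.1f}{s.f1:>8.1f}"
            )
        return "\n".join(rows)

    def to_tsv(self) -> str:
        lines = ["level\ttp\tfp\tfn\tprecision\trecall\tf1"]
        for level in LEVELS:
            s = self.levels[level]
            lines.append(
                f"{level}\t{s.tp}\t{s.fp}\t{s.fn}"
                f"\t{s.precision:.2f}\t{s.recall:.2f}\t{s.f1:.2f}"
            )
        return "\n".join(lines)


def _as_trees(statements) -> list[BELTree]:
    trees = []
    for s in statements:
        trees.append(s if isinstance(s, BELTree) else parse_statement(s))
    return trees


def score_trees(
    gold: dict[str, list], pred: dict[str, list]
) -> ScoreReport:
    """Score per-sentence statement lists (strings or BELTrees)."""
    report = {level: LevelScore() for level in LEVELS}
    sentence_ids = sorted(set(gold) | set(pred))
    for sid in sentence_ids:
        gtrees = _as_trees(gold.get(sid, []))
        ptrees = _as_trees(pred.get(sid, []))
        for level in LEVELS:
            g: Counter = Counter()
            for t in gtrees:
                g += canonicalize(t, level)
            p: Counter = Counter()
            for t in ptrees:
                p += canonicalize(t, level)
            inter = g & p
            tp = sum(inter.values())
            report[level].tp += tp
            report[level].fp += sum(p.values()) - tp
            report[level].fn += sum(g.values()) - tp
    return ScoreReport(report)


def score(gold: dict[str, list[str]], pred: dict[str, list[str]]) -> ScoreReport:
    return score_trees(gold, pred)


def read_statement_file(path) -> dict[str, list[str]]:
    """``sentence_id<TAB>statement`` lines, grouped into per-sentence lists."""
    grouped: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError("expected sentence_id<TAB>statement", line=lineno)
            sid, stmt = parts[0], parts[1].strip()
            if stmt.startswith('"') and stmt.endswith('"'):
                stmt = stmt[1:-1]
            grouped.setdefault(sid, []).append(stmt)
    return grouped


def write_statement_file(grouped: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in grouped:
            for stmt in grouped[sid]:
                fh.write(f"{sid}\t{stmt}\n")
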