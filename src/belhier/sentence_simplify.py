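"""Dependency-based sentence simplification.

A BEL statement condenses the sentence; aligning the full sentence to the
statement's node sequence would leave many stray words.  The sentence is
therefore reduced to the words of the minimal connected subtree of its
dependency parse that contains all statement entities, emitted in original
word order.  Parsing itself is external: trees arrive pre-parsed in CoNLL-U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import FormatError

logger = logging.getLogger(__name__)


@dataclass
class DependencyTree:
    """Single-rooted dependency tree over token positions.

    ``heads[i]`` is the 0-based head of token i, or -1 for the root.
    """

    heads: list[int]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = ["dep"] * len(self.heads)
        self.validate()

    @property
    def root(self) -> int:
        return self.heads.index(-1)

    def __len__(self) -> int:
        return len(self.heads)

    def validate(self) -> None:
        n = len(self.heads)
        roots = [i for i, h in enumerate(self.heads) if h == -1]
        if len(roots) != 1:
            raise FormatError(f"dependency tree must have exactly one root, got {len(roots)}")
        for i, h in enumerate(self.heads):
            if h != -1 and not (0 <= h < n):
                raise FormatError(f"head index {h} of token {i} out of range")
        # cycle check: walk each token to the root
        for i in range(n):
            seen = set()
            node = i
            while node != -1:
                if node in seen:
                    raise FormatError(f"cycle in dependency tree involving token {node}")
                seen.add(node)
                node = self.heads[node]

    def depths(self) -> list[int]:
        depth = [0] * len(self.heads)
        for i in range(len(self.heads)):
            d, node = 0, i
            while self.heads[node] != -1:
                node = self.heads[node]
                d += 1
            depth[i] = d
        return depth


@dataclass
class ConlluSentence:
    sent_id: str
    forms: list[str]
    tree: DependencyTree


def read_conllu(path) -> list[ConlluSentence]:
    """Read a 10-column CoNLL-U file; ``# sent_id`` comments are join keys.

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are skipped.
    """
    sentences: list[ConlluSentence] = []
    sent_id = ""
    forms: list[str] = []
    heads: list[int] = []
    labels: list[str] = []

    def flush(lineno: int):
        nonlocal sent_id, forms, heads, labels
        if forms:
            try:
                tree = DependencyTree(heads, labels)
            except FormatError as e:
                raise FormatError(str(e), line=lineno) from None
            sentences.append(ConlluSentence(sent_id or f"s{len(sentences) + 1}",
                                            forms, tree))
        sent_id, forms, heads, labels = "", [], [], []

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if line.startswith("#"):
                if line[1:].split("=")[0].strip() == "sent_id":
                    sent_id = line.split("=", 1)[1].strip()
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise FormatError("CoNLL-U token line needs >= 8 columns", line=lineno)
            tok_id = cols[0]
            if "-" in tok_id or "." in tok_id:
                continue  # multiword ranges / empty nodes
            try:
                head = int(cols[6])
            except ValueError:
                raise FormatError(f"non-integer HEAD '{cols[6]}'", line=lineno) from None
            forms.append(cols[1])
            heads.append(head - 1)  # CoNLL-U is 1-based, 0 = root
            labels.append(cols[7])
        flush(lineno + 1)
    return sentences


def write_conllu(sentences: list[ConlluSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(f"# sent_id = {s.sent_id}\n")
            for i, form in enumerate(s.forms):
                head = s.tree.heads[i] + 1
                label = s.tree.labels[i]
                fh.write(f"{i + 1}\t{form}\t_\t_\t_\t_\t{head}\t{label}\t_\t_\n")
            fh.write("\n")


def minimal_subtree(tree: DependencyTree, targets) -> set[int]:
    """Nodes of the minimal connected subgraph of *tree* containing *targets*.

    Equals the union of the paths from every target up to their collective
    lowest common ancestor.
    """
    targets = sorted(set(targets))
    if not targets:
        raise ValueError("minimal_subtree requires a non-empty target set")
    n = len(tree)
    for t in targets:
        if not (0 <= t < n):
            raise ValueError(f"target {t} out of range 0..{n - 1}")

    def path_to_root(i: int) -> list[int]:
        chain = [i]
        while tree.heads[chain[-1]] != -1:
            chain.append(tree.heads[chain[-1]])
        return chain

    paths = {t: path_to_root(t) for t in targets}
    common = set(paths[targets[0]])
    for t in targets[1:]:
        common &= set(paths[t])
    depths = tree.depths()
    lca = max(common, key=lambda i: depths[i])

    result: set[int] = {lca}
    for t in targets:
        for node in paths[t]:
            if node == lca:
                break
            result.add(node)
    return result


def simplify(tokens, tree: DependencyTree | None, entity_indices) -> list[int]:
    """Indices (original order) of the minimal subtree covering the entities.

    Degrades to the identity (all indices) when no tree is available.
    """
    n = len(tokens)
    if tree is None:
        logger.warning("no dependency tree available; simplification skipped")
        return list(range(n))
    if len(tree) != n:
        raise FormatError(
            f"dependency tree has {len(tree)} tokens but sentence has {n}"
        )
    entity_indices = sorted(set(entity_indices))
    for i in entity_indices:
        if not (0 <= i < n):
            raise ValueError(f"entity token {i} missing from tree of size {n}")
    keep = minimal_subtree(tree, entity_indices)
    return sorted(keep)
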