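"""Layered BIESO tags: from (tree, alignment) to tags and back.

Every BEL node lives on a layer: entity and parameter leaves on layer 1 and
each internal node one layer above its highest child, so the relation (or
``or``) root sits on the top layer L.  A node's text span is the minimal
contiguous token interval covering its own aligned word(s) and all tokens
covered by its descendants; the span is tagged B/I/E (or S) with the node's
label at the node's layer, everything else is O.  Reconstruction is the
exact inverse: top-layer spans become roots, and each span adopts the spans
nested inside it on lower layers as children, in left-to-right order.

Tag labels carry no arity ("complex", not "complex@2"); arity is recomputed
from the recognized children.  Parameter leaves are tagged with coarse
classes P (modification type), AA (amino-acid code) and NUM (position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .bel_core import (
    BELNode,
    BELTree,
    MOD_FUNCS,
    PLACEHOLDER_PREFIX,
    PLACEHOLDER_RE,
    PREFIX_TYPE,
    RELATIONS,
)
from .errors import FormatError, TagGenerationError
from .text_preproc import AMINO_ONE, AMINO_THREE, Token

logger = logging.getLogger(__name__)

ENTITY_CLASSES = tuple(PLACEHOLDER_PREFIX.values())  # GENE CHEM BP DIS
PARAM_CLASSES = ("P", "AA", "NUM")
LEAF_CLASSES = ENTITY_CLASSES + PARAM_CLASSES


@dataclass
class LayeredTags:
    """layers[k-1] is the BIESO tag sequence of layer k over the tokens."""

    layers: list[list[str]] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.layers)

    def n_tokens(self) -> int:
        return len(self.layers[0]) if self.layers else 0

    def padded(self, L: int) -> "LayeredTags":
        """Pad shallower instances with all-O layers up to L."""
        n = self.n_tokens()
        layers = [list(layer) for layer in self.layers]
        while len(layers) < L:
            layers.append(["O"] * n)
        return LayeredTags(layers)


@dataclass
class LayerAssignment:
    """node id() -> layer; leaves at 1, parents above their highest child."""

    layer_of: dict[int, int]
    L: int

    def __getitem__(self, node: BELNode) -> int:
        return self.layer_of[id(node)]


def assign_layers(tree: BELTree) -> LayerAssignment:
    layer_of: dict[int, int] = {}

    def height(node: BELNode) -> int:
        if node.is_leaf():
            layer_of[id(node)] = 1
            return 1
        h = 1 + max(height(c) for c in node.children)
        layer_of[id(node)] = h
        return h

    return LayerAssignment(layer_of, height(tree.root))


def _param_class_map(tree: BELTree) -> dict[int, str]:
    """Coarse class of every parameter leaf, keyed by node id."""
    classes: dict[int, str] = {}
    for node in tree.root.preorder():
        if node.kind == "function" and node.label in MOD_FUNCS:
            first = True
            for child in node.children:
                if child.kind != "parameter":
                    continue
                if child.label.isdigit():
                    classes[id(child)] = "NUM"
                elif first:
                    classes[id(child)] = "P"
                else:
                    classes[id(child)] = "AA"
                first = False
    for node in tree.root.preorder():
        if node.kind == "parameter" and id(node) not in classes:
            if node.label.isdigit():
                classes[id(node)] = "NUM"
            elif node.label in AMINO_ONE or node.label in AMINO_THREE:
                classes[id(node)] = "AA"
            else:
                classes[id(node)] = "P"
    return classes


def _leaf_class(node: BELNode, param_classes: dict[int, str]) -> str:
    if node.kind == "entity":
        m = PLACEHOLDER_RE.match(node.label)
        if m:
            return m.group(1)
        return PLACEHOLDER_PREFIX.get(node.entity_type or "gene", "GENE")
    return param_classes[id(node)]


def _tag_span(tags: list[str], start: int, end: int, label: str) -> None:
    """Write a BIESO block for [start, end] inclusive."""
    if start == end:
        tags[start] = f"S-{label}"
        return
    tags[start] = f"B-{label}"
    for i in range(start + 1, end):
        tags[i] = f"I-{label}"
    tags[end] = f"E-{label}"


def generate_tags(tokens, tree: BELTree, alignment, layers: LayerAssignment | None = None) -> LayeredTags:
    """Bottom-up layered tagging of *tokens* from the word->node alignment.

    ``alignment`` links source token indices to positions of the tree's
    preorder node sequence.  Raises :class:`TagGenerationError` when a node
    has no aligned word and no recoverable span, or when two same-layer
    spans overlap — such training instances are rejected.
    """
    n = len(tokens)
    nodes = list(tree.root.preorder())
    if layers is None:
        layers = assign_layers(tree)
    param_classes = _param_class_map(tree)

    aligned: dict[int, list[int]] = {idx: [] for idx in range(len(nodes))}
    links = alignment.links if hasattr(alignment, "links") else list(alignment)
    for i, j in links:
        if not (0 <= j < len(nodes)):
            raise TagGenerationError(f"alignment target {j} outside node sequence")
        if not (0 <= i < n):
            raise TagGenerationError(f"alignment source {i} outside sentence")
        aligned[j].append(i)

    node_pos = {id(node): idx for idx, node in enumerate(nodes)}
    spans: dict[int, tuple[int, int]] = {}  # node id -> inclusive interval

    def compute_span(node: BELNode) -> tuple[int, int]:
        own = aligned[node_pos[id(node)]]
        points: list[int] = list(own)
        for child in node.children:
            s, e = compute_span(child)
            points.extend((s, e))
        if not points:
            raise TagGenerationError(
                f"node '{node.label}' has no aligned word and no recoverable span"
            )
        span = (min(points), max(points))
        spans[id(node)] = span
        return span

    compute_span(tree.root)

    tag_layers = [["O"] * n for _ in range(layers.L)]
    occupied: dict[int, list[tuple[int, int]]] = {}
    for node in nodes:
        k = layers[node]
        s, e = spans[id(node)]
        for os_, oe in occupied.setdefault(k, []):
            if s <= oe and os_ <= e:
                raise TagGenerationError(
                    f"overlapping spans at layer {k}: ({os_},{oe}) vs ({s},{e})"
                )
        occupied[k].append((s, e))
        label = _leaf_class(node, param_classes) if node.is_leaf() else node.label
        _tag_span(tag_layers[k - 1], s, e, label)

    return LayeredTags(tag_layers)


# ---------------------------------------------------------------------------
# BIESO span utilities


def repair_bieso(tags: list[str]) -> list[str]:
    """Deterministic repair of a predicted BIESO sequence.

    I/E without an open block becomes B; an unterminated B/I block is closed
    at its last contiguous token (turned into E, or S for width 1).
    """
    out = list(tags)
    open_start: int | None = None
    open_label: str | None = None

    def close(end: int) -> None:
        nonlocal open_start, open_label
        if open_start is None:
            return
        if end == open_start:
            out[open_start] = f"S-{open_label}"
        else:
            out[end] = f"E-{open_label}"
        open_start, open_label = None, None

    for i, tag in enumerate(out):
        if tag == "O":
            close(i - 1)
            continue
        prefix, label = tag.split("-", 1)
        if prefix == "S":
            close(i - 1)
        elif prefix == "B":
            close(i - 1)
            open_start, open_label = i, label
            out[i] = f"B-{label}"
        elif prefix in ("I", "E"):
            if open_start is None or open_label != label:
                close(i - 1)
                open_start, open_label = i, label
                out[i] = f"B-{label}"
            elif prefix == "E":
                out[i] = f"E-{label}"
                open_start, open_label = None, None
    close(len(out) - 1)
    return out


def spans_of(tags: list[str]) -> list[tuple[int, int, str]]:
    """(start, end inclusive, label) spans of a well-formed BIESO sequence."""
    spans = []
    start, label = None, None
    for i, tag in enumerate(tags):
        if tag == "O":
            continue
        prefix, lab = tag.split("-", 1)
        if prefix == "S":
            spans.append((i, i, lab))
        elif prefix == "B":
            start, label = i, lab
        elif prefix == "E" and start is not None:
            spans.append((start, i, label))
            start, label = None, None
    return spans


# ---------------------------------------------------------------------------
# reconstruction


def _leaf_node(label_class: str, surface: str) -> BELNode:
    if label_class in PREFIX_TYPE:
        return BELNode("entity", surface, entity_type=PREFIX_TYPE[label_class])
    return BELNode("parameter", surface)


def tags_to_tree(tags: LayeredTags, tokens) -> BELTree | None:
    """Top-down reconstruction of the BEL tree from layered tags.

    Returns None when no top-layer span exists (no statement extracted).
    Orphan lower spans outside every higher span are dropped with a warning.
    Multiple top-layer spans are joined under an ``or`` root.
    """
    surfaces = [t.surface if isinstance(t, Token) else str(t) for t in tokens]
    all_spans: list[tuple[int, int, int, str]] = []  # (layer, start, end, label)
    for k, layer in enumerate(tags.layers, start=1):
        for s, e, label in spans_of(repair_bieso(layer)):
            all_spans.append((k, s, e, label))
    if not all_spans:
        return None
    top = max(k for k, *_ in all_spans)
    top_spans = [sp for sp in all_spans if sp[0] == top]

    # parent of a span: the containing span on the lowest higher layer,
    # narrowest first, ties leftmost
    children: dict[tuple, list[tuple]] = {sp: [] for sp in all_spans}
    for sp in all_spans:
        k, s, e, _ = sp
        if k == top:
            continue
        candidates = [
            other
            for other in all_spans
            if other[0] > k and other[1] <= s and e <= other[2]
        ]
        if not candidates:
            logger.warning("dropping orphan span %s outside every higher span", sp)
            continue
        parent = min(candidates, key=lambda o: (o[0], o[2] - o[1], o[1]))
        children[parent].append(sp)

    def build(sp: tuple) -> BELNode:
        k, s, e, label = sp
        kids = sorted(children[sp], key=lambda o: o[1])
        if k == 1:
            return _leaf_node(label, surfaces[s] if s == e else " ".join(surfaces[s : e + 1]))
        if label == "or":
            kind = "or"
        elif label in RELATIONS:
            kind = "relation"
        else:
            kind = "function"
        return BELNode(kind, label, [build(c) for c in kids])

    roots = [build(sp) for sp in sorted(top_spans, key=lambda o: o[1])]
    if len(roots) == 1:
        return BELTree(roots[0])
    return BELTree(BELNode("or", "or", roots))


# ---------------------------------------------------------------------------
# CoNLL-style tag file I/O


def write_tag_file(instances, path) -> None:
    """``token  tag1 ... tagL`` columns, blank line between sentences."""
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, tags in instances:
            surfaces = [t.surface if isinstance(t, Token) else str(t) for t in tokens]
            for i, surface in enumerate(surfaces):
                cols = [surface] + [layer[i] for layer in tags.layers]
                fh.write("\t".join(cols) + "\n")
            fh.write("\n")


def read_tag_file(path):
    instances = []
    tokens: list[str] = []
    rows: list[list[str]] = []

    def flush():
        nonlocal tokens, rows
        if tokens:
            L = len(rows[0])
            layers = [[row[k] for row in rows] for k in range(L)]
            instances.append((tokens, LayeredTags(layers)))
        tokens, rows = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError("tag line needs token + >=1 layer", line=lineno)
            tokens.append(cols[0])
            rows.append(cols[1:])
            if len(cols) != len(rows[0]) + 1:
                raise FormatError("inconsistent layer count", line=lineno)
    flush()
    return instances
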