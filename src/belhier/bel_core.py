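"""Core model of BEL statements as trees.

A BEL statement such as ``cat(p(HGNC:IL2)) increases complex(p(HGNC:LYN),
p(HGNC:IL2RB))`` is represented as a tree whose root is the causal relation,
whose internal nodes are BEL functions (``complex``, ``cat``, ``pmod`` ...)
and whose leaves are entities (``HGNC:IL2``) or literal parameters (``P``,
``S``, ``21``).  The module covers the statement life cycle used by the
extraction pipeline:

* parsing statement text into trees and rendering trees back to text;
* normalization — protein-modification functions (``pmod``, ``sub``,
  ``trunc``, ``fus``) written inside an entity term are elevated above it so
  that functions always sit above entities in the hierarchy;
* unification of the several statements attached to one sentence under a
  single ``or`` root, and the inverse split;
* serialization of a tree to its preorder node sequence with ``@n`` arity
  markers (``decreases@2 CHEM_1 complex@2 GENE_1 GENE_2``) and the exact
  inverse deserialization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import (
    BELParseError,
    MalformedSequenceError,
    RenderError,
    UnsupportedRelationError,
)

RELATIONS = ("increases", "decreases", "directlyIncreases", "directlyDecreases")
DIRECT_TO_BASE = {"directlyIncreases": "increases", "directlyDecreases": "decreases"}

#: modification functions elevated above the entity term during normalization
MOD_FUNCS = ("pmod", "sub", "trunc", "fus")

#: BEL term functions wrapping a bare entity, with the entity type they imply
TERM_FUNCS = {
    "p": "gene",
    "g": "gene",
    "r": "gene",
    "m": "gene",
    "a": "chem",
    "bp": "bp",
    "path": "dis",
}
TYPE_TO_TERM = {"gene": "p", "chem": "a", "bp": "bp", "dis": "path"}

NAMESPACE_TYPES = {
    "HGNC": "gene",
    "MGI": "gene",
    "EGID": "gene",
    "CHEBI": "chem",
    "GOBP": "bp",
    "MESHD": "dis",
}

PLACEHOLDER_PREFIX = {"gene": "GENE", "chem": "CHEM", "bp": "BP", "dis": "DIS"}
PREFIX_TYPE = {v: k for k, v in PLACEHOLDER_PREFIX.items()}
PLACEHOLDER_RE = re.compile(r"^(GENE|CHEM|BP|DIS)_(\d+)$")

_BARE_IDENT_RE = re.compile(r"^[\w\-.']+$")


@dataclass
class BELNode:
    """One node of a BEL tree.

    kind is one of ``relation``, ``function``, ``entity``, ``parameter``,
    ``or``.  Entities carry either a ``namespace:identifier`` label or an
    anonymized placeholder (``GENE_1``); their biological type (gene / chem /
    bp / dis) is kept on ``entity_type``.
    """

    kind: str
    label: str
    children: list["BELNode"] = field(default_factory=list)
    entity_type: str | None = None

    def is_leaf(self) -> bool:
        return self.kind in ("entity", "parameter")

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def copy(self) -> "BELNode":
        return BELNode(
            self.kind, self.label, [c.copy() for c in self.children], self.entity_type
        )


@dataclass
class BELTree:
    """A complete statement (or an ``or``-unified bundle of statements)."""

    root: BELNode
    source_statement: str = ""

    def __eq__(self, other):
        return isinstance(other, BELTree) and self.root == other.root

    def copy(self) -> "BELTree":
        return BELTree(self.root.copy(), self.source_statement)

    def entity_leaves(self) -> list[BELNode]:
        return [n for n in self.root.preorder() if n.kind == "entity"]


# ---------------------------------------------------------------------------
# parsing


def _lex(text: str) -> list[tuple[str, int]]:
    """Split statement text into (token, offset) pairs.

    Quoted segments (``GOBP:"cell cycle"``) are kept inside their token.
    """
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "(),":
            tokens.append((c, i))
            i += 1
        else:
            start = i
            buf = []
            while i < n and text[i] not in "()," and not text[i].isspace():
                if text[i] == '"':
                    close = text.find('"', i + 1)
                    if close < 0:
                        raise BELParseError("unterminated quote", offset=i)
                    buf.append(text[i : close + 1])
                    i = close + 1
                else:
                    buf.append(text[i])
                    i += 1
            tokens.append(("".join(buf), start))
    return tokens


def _check_balance(tokens: list[tuple[str, int]]) -> None:
    depth = 0
    for tok, off in tokens:
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise BELParseError("unbalanced ')'", offset=off)
    if depth != 0:
        last = tokens[-1][1] if tokens else 0
        raise BELParseError("unbalanced '(': missing closing parenthesis", offset=last)


def _entity_from_identifier(token: str, entity_type: str | None = None) -> BELNode:
    m = PLACEHOLDER_RE.match(token)
    if m:
        return BELNode("entity", token, entity_type=PREFIX_TYPE[m.group(1)])
    namespace, ident = token.split(":", 1)
    ident = ident.strip('"')
    etype = entity_type or NAMESPACE_TYPES.get(namespace)
    return BELNode("entity", f"{namespace}:{ident}", entity_type=etype)


def _make_leaf(token: str) -> BELNode:
    if ":" in token or PLACEHOLDER_RE.match(token):
        return _entity_from_identifier(token)
    return BELNode("parameter", token)


def _make_call(name: str, args: list[BELNode]) -> BELNode:
    if name in TERM_FUNCS:
        etype = TERM_FUNCS[name]
        typed = []
        for a in args:
            if a.kind == "entity":
                typed.append(replace(a, entity_type=etype))
            else:
                typed.append(a)
        args = typed
        if len(args) == 1 and args[0].kind == "entity":
            return args[0]
        # un-normalized entity term (e.g. p(HGNC:AKT1, pmod(P, S, 21)))
        return BELNode("function", name, args)
    return BELNode("function", name, args)


def _parse_node(tokens: list[tuple[str, int]], pos: int) -> tuple[BELNode, int]:
    if pos >= len(tokens):
        raise BELParseError("unexpected end of statement")
    name, off = tokens[pos]
    if name in "(),":
        raise BELParseError(f"unexpected '{name}'", offset=off)
    if name in RELATIONS:
        raise UnsupportedRelationError(
            f"nested relation '{name}' inside a term is not supported"
        )
    if pos + 1 < len(tokens) and tokens[pos + 1][0] == "(":
        pos += 2
        args: list[BELNode] = []
        while True:
            if pos >= len(tokens):
                raise BELParseError("unexpected end inside term", offset=off)
            if tokens[pos][0] == ")":
                pos += 1
                break
            arg, pos = _parse_node(tokens, pos)
            args.append(arg)
            if pos < len(tokens) and tokens[pos][0] == ",":
                pos += 1
            elif pos < len(tokens) and tokens[pos][0] == ")":
                pos += 1
                break
            else:
                bad = tokens[pos] if pos < len(tokens) else (None, None)
                raise BELParseError("expected ',' or ')'", offset=bad[1])
        if not args:
            raise BELParseError(f"empty argument list for '{name}'", offset=off)
        return _make_call(name, args), pos
    return _make_leaf(name), pos + 1


def _parse_term(tokens: list[tuple[str, int]]) -> BELNode:
    if not tokens:
        raise BELParseError("empty term")
    node, pos = _parse_node(tokens, 0)
    if pos != len(tokens):
        raise BELParseError("trailing tokens after term", offset=tokens[pos][1])
    return node


def parse_statement(text: str) -> BELTree:
    """Parse one BEL statement into a tree rooted at its relation.

    The relation keyword must occur exactly once at the top parenthesis
    level; its left/right arguments become the root's children in original
    order.
    """
    tokens = _lex(text)
    _check_balance(tokens)
    depth = 0
    rel_positions = []
    top_words = []
    for idx, (tok, off) in enumerate(tokens):
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
        elif depth == 0 and tok not in ",":
            top_words.append((idx, tok))
            if tok in RELATIONS:
                rel_positions.append(idx)
    if not rel_positions:
        candidates = [t for i, t in top_words if "(" not in t and ":" not in t]
        raise UnsupportedRelationError(
            f"no supported relation keyword found (top-level words: {candidates})"
        )
    if len(rel_positions) > 1:
        raise UnsupportedRelationError("more than one top-level relation keyword")
    rel_idx = rel_positions[0]
    relation = tokens[rel_idx][0]
    left = _parse_term(tokens[:rel_idx])
    right = _parse_term(tokens[rel_idx + 1 :])
    return BELTree(BELNode("relation", relation, [left, right]), source_statement=text)


# ---------------------------------------------------------------------------
# normalization


def _normalize_node(node: BELNode) -> BELNode:
    children = [_normalize_node(c) for c in node.children]
    if node.kind == "function" and node.label in TERM_FUNCS:
        entities = [c for c in children if c.kind == "entity"]
        mods = [c for c in children if c.kind == "function" and c.label in MOD_FUNCS]
        if len(entities) == 1 and mods and len(entities) + len(mods) == len(children):
            current = entities[0]
            if current.entity_type is None:
                current = replace(current, entity_type=TERM_FUNCS[node.label])
            for mod in mods:
                current = BELNode("function", mod.label, [current] + mod.children)
            return current
    return BELNode(node.kind, node.label, children, node.entity_type)


def normalize_statement(tree: BELTree) -> BELTree:
    """Elevate modification functions above their entity term.

    ``p(HGNC:AKT1, pmod(P, S, 21))`` becomes ``pmod(p(HGNC:AKT1), P, S, 21)``
    so that no entity has a function among its arguments.  Idempotent.
    """
    return BELTree(_normalize_node(tree.root), tree.source_statement)


def dedupe_trees(trees: list[BELTree]) -> list[BELTree]:
    """Drop exact duplicates (after normalization) attached to one sentence."""
    seen: list[BELTree] = []
    for t in trees:
        if not any(t == s for s in seen):
            seen.append(t)
    return seen


# ---------------------------------------------------------------------------
# unification


def unify_trees(trees: list[BELTree]) -> BELTree:
    """Merge the statements of one sentence under a single ``or`` root."""
    if not trees:
        raise ValueError("unify_trees requires at least one tree")
    if len(trees) == 1:
        return trees[0]
    root = BELNode("or", "or", [t.root for t in trees])
    return BELTree(root, " | ".join(t.source_statement for t in trees))


def split_unified(tree: BELTree) -> list[BELTree]:
    """Inverse of :func:`unify_trees`."""
    if tree.root.kind == "or":
        return [BELTree(child) for child in tree.root.children]
    return [tree]


# ---------------------------------------------------------------------------
# placeholders


def build_placeholder_map(trees: list[BELTree] | BELTree) -> dict[str, str]:
    """Number entities GENE_1, CHEM_1 ... by first preorder mention per type."""
    if isinstance(trees, BELTree):
        trees = [trees]
    counters: dict[str, int] = {}
    mapping: dict[str, str] = {}
    for tree in trees:
        for node in tree.root.preorder():
            if node.kind != "entity" or node.label in mapping:
                continue
            if PLACEHOLDER_RE.match(node.label):
                continue
            etype = node.entity_type or "gene"
            counters[etype] = counters.get(etype, 0) + 1
            mapping[node.label] = f"{PLACEHOLDER_PREFIX[etype]}_{counters[etype]}"
    return mapping


def apply_placeholders(tree: BELTree, mapping: dict[str, str]) -> BELTree:
    """Return a copy of *tree* with entity labels replaced by placeholders."""

    def visit(node: BELNode) -> BELNode:
        if node.kind == "entity" and node.label in mapping:
            return BELNode("entity", mapping[node.label], entity_type=node.entity_type)
        return BELNode(node.kind, node.label, [visit(c) for c in node.children],
                       node.entity_type)

    return BELTree(visit(tree.root), tree.source_statement)


# ---------------------------------------------------------------------------
# serialization


def serialize_tree(tree: BELTree, placeholder_map: dict[str, str] | None = None) -> list[str]:
    """Preorder node sequence with ``@n`` arity markers.

    Internal nodes render as ``label@n`` (n = child count), entity leaves as
    typed placeholders, parameter leaves verbatim.  Entities already labeled
    with placeholders pass through; otherwise ``placeholder_map`` must cover
    them.
    """
    out: list[str] = []

    def visit(node: BELNode) -> None:
        if node.kind in ("relation", "function", "or"):
            out.append(f"{node.label}@{len(node.children)}")
            for child in node.children:
                visit(child)
        elif node.kind == "entity":
            if placeholder_map and node.label in placeholder_map:
                out.append(placeholder_map[node.label])
            elif PLACEHOLDER_RE.match(node.label):
                out.append(node.label)
            else:
                raise KeyError(f"entity '{node.label}' missing from placeholder map")
        else:
            out.append(node.label)

    visit(tree.root)
    return out


_ARITY_RE = re.compile(r"^(.+)@(\d+)$")


def deserialize_sequence(seq: list[str]) -> BELTree:
    """Rebuild the unique tree encoded by an arity-annotated node sequence."""
    if not seq:
        raise MalformedSequenceError("empty node sequence")

    pos = 0

    def consume() -> BELNode:
        nonlocal pos
        if pos >= len(seq):
            raise MalformedSequenceError(
                f"arity underflow: sequence exhausted at position {pos}"
            )
        token = seq[pos]
        pos += 1
        m = _ARITY_RE.match(token)
        if m:
            label, arity = m.group(1), int(m.group(2))
            children = [consume() for _ in range(arity)]
            if label == "or":
                kind = "or"
            elif label in RELATIONS:
                kind = "relation"
            else:
                kind = "function"
            return BELNode(kind, label, children)
        pm = PLACEHOLDER_RE.match(token)
        if pm:
            return BELNode("entity", token, entity_type=PREFIX_TYPE[pm.group(1)])
        if ":" in token:
            return _entity_from_identifier(token)
        return BELNode("parameter", token)

    root = consume()
    if pos != len(seq):
        raise MalformedSequenceError(
            f"arity overflow: {len(seq) - pos} leftover token(s)"
        )
    return BELTree(root)


# ---------------------------------------------------------------------------
# rendering


def _resolve_entity(
    node: BELNode, entities: dict[str, tuple[str, str, str]] | None
) -> tuple[str, str, str]:
    if PLACEHOLDER_RE.match(node.label):
        if not entities or node.label not in entities:
            raise RenderError(f"unresolvable placeholder '{node.label}'")
        return entities[node.label]
    namespace, ident = node.label.split(":", 1)
    etype = node.entity_type or NAMESPACE_TYPES.get(namespace, "gene")
    return namespace, ident, etype


def _quote_identifier(ident: str) -> str:
    return ident if _BARE_IDENT_RE.match(ident) else f'"{ident}"'


def _entity_term(node: BELNode, entities) -> str:
    namespace, ident, etype = _resolve_entity(node, entities)
    return f"{TYPE_TO_TERM[etype]}({namespace}:{_quote_identifier(ident)})"


def _render_node(node: BELNode, entities) -> str:
    if node.kind == "entity":
        return _entity_term(node, entities)
    if node.kind == "parameter":
        return node.label
    if node.kind == "function":
        if (
            node.label in MOD_FUNCS
            and node.children
            and node.children[0].kind == "entity"
        ):
            # push the modification back inside the entity term
            namespace, ident, etype = _resolve_entity(node.children[0], entities)
            params = ",".join(_render_node(c, entities) for c in node.children[1:])
            return (
                f"{TYPE_TO_TERM[etype]}({namespace}:{_quote_identifier(ident)},"
                f"{node.label}({params}))"
            )
        args = ",".join(_render_node(c, entities) for c in node.children)
        return f"{node.label}({args})"
    raise RenderError(f"cannot render node of kind '{node.kind}' inside a term")


def render_statement(
    tree: BELTree, entities: dict[str, tuple[str, str, str]] | None = None
) -> str:
    """Render a plain (non-``or``) tree back to BEL text.

    ``entities`` maps placeholders to ``(namespace, identifier, type)``.
    Modification-function elevation is reversed, entity types become BEL term
    functions (p/a/bp/path), commas carry no trailing space.
    """
    root = tree.root
    if root.kind == "or":
        raise RenderError("split a unified tree before rendering")
    if root.kind != "relation":
        raise RenderError(f"statement root must be a relation, got '{root.kind}'")
    if len(root.children) != 2:
        raise RenderError(
            f"relation '{root.label}' has {len(root.children)} argument(s), needs 2"
        )
    left = _render_node(root.children[0], entities)
    right = _render_node(root.children[1], entities)
    return f"{left} {root.label} {right}"


def canonicalize_statement_text(text: str) -> str:
    """Normalize the whitespace dialect for statement-string comparison."""
    text = re.sub(r"\s+", " ", text.strip())
    text = re.sub(r",\s+", ",", text)
    text = re.sub(r"\(\s+", "(", text)
    text = re.sub(r"\s+\)", ")", text)
    return text


# ---------------------------------------------------------------------------
# statement file I/O


def read_statement_lines(path) -> list[str]:
    """One statement per line; optional surrounding quotes, annotations after a tab."""
    statements = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            stmt = line.split("\t", 1)[0].strip()
            if stmt.startswith('"') and stmt.endswith('"'):
                stmt = stmt[1:-1]
            statements.append(stmt)
    return statements


def write_node_sequences(seqs: list[list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(" ".join(seq) + "\n")


def read_node_sequences(path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.split() for line in fh if line.strip()]
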