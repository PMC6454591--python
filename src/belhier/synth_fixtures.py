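"""Seeded generator of sentence/statement pairs with full gold structure.

Each generated pair mimics the shape of real sentence/BEL-statement pairs:
a subject phrase, a relation trigger word drawn from a small causal lexicon
("prevented" -> decreases, "elevated" -> increases ...), an optional
function trigger ("association" -> complex, "catalysis" -> cat ...), filler
distractor words attached off the entity paths of a deterministic
dependency tree (so simplification provably removes them), and optional
trigger-word corruption noise.  Because the pair is built from its tree,
the gold word alignment, the gold layered tags and the gold dependency
parse are all known, which makes every pipeline stage testable without any
external corpus.

The generator also provides random BEL trees for round-trip property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .bel_core import (
    BELNode,
    BELTree,
    apply_placeholders,
    normalize_statement,
    render_statement,
    serialize_tree,
    unify_trees,
)
from .hier_tagging import LayeredTags, assign_layers, generate_tags
from .parallel_align import Alignment, ParallelPair, format_pharaoh
from .sentence_simplify import ConlluSentence, DependencyTree, simplify, write_conllu
from .text_preproc import (
    AnnotatedSentence,
    AnonymizationMap,
    Mention,
    Token,
    anonymize,
    stem,
)

RELATION_TRIGGERS = {
    "prevented": "decreases",
    "suppressed": "decreases",
    "reduced": "decreases",
    "abolished": "decreases",
    "elevated": "increases",
    "induced": "increases",
    "promoted": "increases",
    "enhanced": "increases",
}

#: object-side function triggers with their BEL function and arity
FUNCTION_TRIGGERS = {
    "association": ("complex", 2),
    "binding": ("complex", 2),
    "catalysis": ("cat", 1),
    "degradation": ("deg", 1),
}

#: subject-side activity triggers (always unary)
SUBJECT_FUNCTION_TRIGGERS = {
    "catalysis": "cat",
    "activity": "act",
}

DISTRACTORS = (
    "notably", "markedly", "significantly", "strongly", "recently",
    "consistently", "furthermore", "surprisingly",
)

#: nominalization phrases heading the subject ("Preincubation with CHEM_1
#: prevented ..."); their head word sits on the dependency path, so they
#: survive simplification yet stay unaligned in the gold alignment
SUBJECT_PREP_PHRASES = (
    ("Preincubation", "with"),
    ("Exposure", "to"),
    ("Treatment", "with"),
    ("incubation", "with"),
    ("stimulation", "of"),
)

#: connector introducing the second argument of a two-place function
SECOND_ARG_CONNECTORS = ("to", "with")

#: phrasal relation triggers: head word carries the relation, the particle
#: is an unaligned filler on the dependency path — keeps "to"/"with"
#: frequent outside complex() clauses, as in real prose
PHRASAL_TRIGGERS = {
    ("led", "to"): "increases",
    ("contributed", "to"): "increases",
    ("interfered", "with"): "decreases",
}

_TYPE_WEIGHTS = (("gene", 6), ("chem", 2), ("bp", 1), ("dis", 1))
_NAMESPACE = {"gene": "HGNC", "chem": "CHEBI", "bp": "GOBP", "dis": "MESHD"}


@dataclass
class GenConfig:
    n_pairs: int = 100
    seed: int = 0
    n_genes: int = 30
    n_chems: int = 12
    n_bps: int = 8
    n_dis: int = 4
    p_function: float = 0.5
    p_subject_activity: float = 0.25
    p_subject_prep: float = 0.3
    p_phrasal_trigger: float = 0.25
    p_or: float = 0.1
    p_distractor: float = 0.3
    p_noise: float = 0.05
    relation_triggers: dict = field(default_factory=lambda: dict(RELATION_TRIGGERS))
    function_triggers: dict = field(default_factory=lambda: dict(FUNCTION_TRIGGERS))

    @classmethod
    def low_noise(cls, n_pairs: int, seed: int) -> "GenConfig":
        """Single-statement study configuration (L = 3, mild trigger noise)."""
        return cls(n_pairs=n_pairs, seed=seed, p_or=0.0)

    def vocab(self) -> dict[str, list[str]]:
        return {
            "gene": [f"GP{i}" for i in range(1, self.n_genes + 1)],
            "chem": [f"CHX{i}" for i in range(1, self.n_chems + 1)],
            "bp": [f"BPX{i}" for i in range(1, self.n_bps + 1)],
            "dis": [f"DSX{i}" for i in range(1, self.n_dis + 1)],
        }


@dataclass
class SynthPair:
    pair_id: str
    sentence: AnnotatedSentence  # raw (entity names in text)
    anon_sentence: AnnotatedSentence  # placeholders in text
    anon_map: AnonymizationMap
    dep_tree: DependencyTree
    statements: list[BELTree]  # entity labels are namespace:identifier
    unified: BELTree  # placeholder-labeled unified tree
    entity_table: dict[str, tuple[str, str, str]]  # placeholder -> (ns, id, type)
    simplified_indices: list[int]
    simplified_tokens: list[Token]
    node_sequence: list[str]
    gold_alignment: Alignment
    gold_tags: LayeredTags
    L: int
    flags: dict = field(default_factory=dict)

    def parallel_pair(self) -> ParallelPair:
        return ParallelPair(
            self.pair_id,
            [t.surface for t in self.simplified_tokens],
            list(self.node_sequence),
            gold_alignment=list(self.gold_alignment.links),
        )


class _Clause:
    """One statement clause: tokens with roles and intra-clause heads."""

    def __init__(self):
        self.tokens: list[str] = []  # surfaces
        self.heads: list[int] = []  # relative indices, -1 = clause root
        self.roles: list[tuple[str, object] | None] = []  # (role, payload)
        self.root_rel: int = -1

    def add(self, surface: str, head: int, role=None) -> int:
        self.tokens.append(surface)
        self.heads.append(head)
        self.roles.append(role)
        return len(self.tokens) - 1


def _pick_entity(rng: random.Random, vocab, used) -> tuple[str, str]:
    """(type, name) of a fresh entity for the current sentence."""
    types = [t for t, w in _TYPE_WEIGHTS for _ in range(w)]
    for _ in range(20):
        etype = rng.choice(types)
        candidates = [n for n in vocab[etype] if (etype, n) not in used]
        if candidates:
            name = rng.choice(candidates)
            used.add((etype, name))
            return etype, name
    raise ValueError("entity vocabulary too small for the requested sentence")


def _corrupt(rng: random.Random, word: str) -> str:
    pos = rng.randrange(len(word))
    return word[:pos] + rng.choice("xzq") + word[pos:]


def _build_clause(rng: random.Random, cfg: GenConfig, vocab, used, flags) -> tuple[_Clause, BELNode]:
    """One relation clause plus its (namespace-labeled) statement tree."""
    clause = _Clause()
    use_phrasal = rng.random() < cfg.p_phrasal_trigger
    if use_phrasal:
        trigger_word, particle = rng.choice(sorted(PHRASAL_TRIGGERS))
        relation = PHRASAL_TRIGGERS[(trigger_word, particle)]
    else:
        particle = None
        trigger_word = rng.choice(sorted(cfg.relation_triggers))
        relation = cfg.relation_triggers[trigger_word]

    subj_type, subj_name = _pick_entity(rng, vocab, used)
    subj_entity = BELNode(
        "entity", f"{_NAMESPACE[subj_type]}:{subj_name}", entity_type=subj_type
    )
    use_subj_func = rng.random() < cfg.p_subject_activity
    obj_is_func = rng.random() < cfg.p_function
    flags["has_function"] = obj_is_func
    flags["has_subject_activity"] = use_subj_func

    # clause-relative indices; trigger is the clause root
    # layout: [distractor?] subject-part trigger [distractor?] object-part
    pre_distract = rng.random() < cfg.p_distractor
    post_distract = rng.random() < cfg.p_distractor

    if pre_distract:
        clause.add(rng.choice(DISTRACTORS), head=-2, role=("distractor", None))

    if use_subj_func:
        sf_word = rng.choice(sorted(SUBJECT_FUNCTION_TRIGGERS))
        sf_func = SUBJECT_FUNCTION_TRIGGERS[sf_word]
        i_sf = clause.add(sf_word, head=-2, role=("subj_func", None))
        i_of = clause.add("of", head=i_sf)
        clause.add(subj_name, head=i_of, role=("entity", (subj_type, subj_name)))
        subject = BELNode("function", sf_func, [subj_entity])
    elif rng.random() < cfg.p_subject_prep:
        head_word, prep = SUBJECT_PREP_PHRASES[
            rng.randrange(len(SUBJECT_PREP_PHRASES))
        ]
        i_h = clause.add(head_word, head=-2)
        i_p = clause.add(prep, head=i_h)
        clause.add(subj_name, head=i_p, role=("entity", (subj_type, subj_name)))
        subject = subj_entity
    else:
        clause.add(subj_name, head=-2, role=("entity", (subj_type, subj_name)))
        subject = subj_entity

    noisy = rng.random() < cfg.p_noise
    surface_trigger = _corrupt(rng, trigger_word) if noisy else trigger_word
    flags["noisy_trigger"] = noisy
    i_trig = clause.add(surface_trigger, head=-1, role=("relation", None))
    clause.root_rel = i_trig
    for i, h in enumerate(clause.heads):
        if h == -2:
            clause.heads[i] = i_trig
    i_attach = clause.add(particle, head=i_trig) if particle else i_trig

    if obj_is_func:
        f_word = rng.choice(sorted(cfg.function_triggers))
        f_name, arity = cfg.function_triggers[f_word]
        i_f = clause.add(f_word, head=i_attach, role=("obj_func", None))
        i_of = clause.add("of", head=i_f)
        obj_type, obj_name = _pick_entity(rng, vocab, used)
        i_o1 = clause.add(obj_name, head=i_of, role=("entity", (obj_type, obj_name)))
        children = [BELNode("entity", f"{_NAMESPACE[obj_type]}:{obj_name}",
                            entity_type=obj_type)]
        if arity == 2:
            connector = SECOND_ARG_CONNECTORS[rng.randrange(len(SECOND_ARG_CONNECTORS))]
            i_to = clause.add(connector, head=i_o1)
            obj2_type, obj2_name = _pick_entity(rng, vocab, used)
            clause.add(obj2_name, head=i_to, role=("entity", (obj2_type, obj2_name)))
            children.append(
                BELNode("entity", f"{_NAMESPACE[obj2_type]}:{obj2_name}",
                        entity_type=obj2_type)
            )
        obj = BELNode("function", f_name, children)
    else:
        obj_type, obj_name = _pick_entity(rng, vocab, used)
        clause.add(obj_name, head=i_attach, role=("entity", (obj_type, obj_name)))
        obj = BELNode("entity", f"{_NAMESPACE[obj_type]}:{obj_name}",
                      entity_type=obj_type)

    if post_distract:
        clause.add(rng.choice(DISTRACTORS), head=i_trig, role=("distractor", None))

    root = BELNode("relation", relation, [subject, obj])
    return clause, root


def _generate_pair(rng: random.Random, cfg: GenConfig, vocab, index: int) -> SynthPair:
    pair_id = f"synth-{index:05d}"
    used: set = set()
    flags: dict = {}
    is_or = rng.random() < cfg.p_or
    flags["is_or"] = is_or

    clause_flags: dict = {}
    clauses = [_build_clause(rng, cfg, vocab, used, clause_flags)]
    flags.update(clause_flags)
    if is_or:
        clauses.append(_build_clause(rng, cfg, vocab, used, {}))

    # assemble sentence tokens + global dependency tree
    surfaces: list[str] = []
    heads: list[int] = []
    roles: list = []
    clause_roots: list[int] = []
    for ci, (clause, _) in enumerate(clauses):
        if ci > 0:
            surfaces.append("and")
            heads.append(clause_roots[0])
            roles.append(("conj_marker", None))
        offset = len(surfaces)
        for rel_head, surface, role in zip(clause.heads, clause.tokens, clause.roles):
            surfaces.append(surface)
            if rel_head == -1:
                heads.append(-1 if ci == 0 else clause_roots[0])
            else:
                heads.append(rel_head + offset)
            roles.append(role)
        clause_roots.append(offset + clause.root_rel)

    text = " ".join(surfaces)
    tokens: list[Token] = []
    pos = 0
    for surface in surfaces:
        tokens.append(Token(surface, pos, pos + len(surface), stem=stem(surface)))
        pos += len(surface) + 1

    mentions = [
        Mention(i, i + 1, role[1][0], f"{_NAMESPACE[role[1][0]]}:{role[1][1]}")
        for i, role in enumerate(roles)
        if role and role[0] == "entity"
    ]
    sentence = AnnotatedSentence(pair_id, text, tokens, mentions)
    dep_tree = DependencyTree(list(heads))

    anon_sentence, anon_map = anonymize(sentence)
    placeholder_of = {m.entity_id: m.placeholder for m in anon_sentence.mentions}
    entity_table = {
        m.placeholder: (m.entity_id.split(":", 1)[0], m.entity_id.split(":", 1)[1],
                        m.entity_type)
        for m in anon_sentence.mentions
    }

    statements = [
        normalize_statement(BELTree(root)) for _, root in clauses
    ]
    placeholder_trees = [
        apply_placeholders(t, placeholder_of) for t in statements
    ]
    unified = unify_trees([t.copy() for t in placeholder_trees])

    entity_indices = [m.start_token for m in anon_sentence.mentions]
    simplified_indices = simplify(anon_sentence.tokens, dep_tree, entity_indices)
    simplified_tokens = [anon_sentence.tokens[i] for i in simplified_indices]
    new_index = {orig: new for new, orig in enumerate(simplified_indices)}

    node_sequence = serialize_tree(unified)
    preorder = list(unified.root.preorder())
    node_pos = {id(n): i for i, n in enumerate(preorder)}

    # walk unified tree and clause roles in parallel to build gold links
    links: list[tuple[int, int]] = []
    statement_roots = (
        list(unified.root.children) if unified.root.kind == "or" else [unified.root]
    )
    token_cursor = 0
    for ci, ((clause, _), stmt_root) in enumerate(zip(clauses, statement_roots)):
        if ci > 0:
            token_cursor += 1  # the "and" marker
        offset = token_cursor
        relation_node = stmt_root
        subject_node, object_node = stmt_root.children
        for rel_i, role in enumerate(clause.roles):
            tok_i = offset + rel_i
            if tok_i not in new_index:
                continue
            si = new_index[tok_i]
            if role is None or role[0] in ("distractor", "conj_marker"):
                continue
            if role[0] == "relation":
                links.append((si, node_pos[id(relation_node)]))
            elif role[0] == "subj_func":
                links.append((si, node_pos[id(subject_node)]))
            elif role[0] == "obj_func":
                links.append((si, node_pos[id(object_node)]))
            elif role[0] == "entity":
                etype, name = role[1]
                placeholder = placeholder_of[f"{_NAMESPACE[etype]}:{name}"]
                for node in stmt_root.preorder():
                    if node.kind == "entity" and node.label == placeholder:
                        candidate = node_pos[id(node)]
                        if all(j != candidate for _, j in links):
                            links.append((si, candidate))
                            break
        token_cursor += len(clause.tokens)

    gold_alignment = Alignment(links=sorted(links))
    layers = assign_layers(unified)
    gold_tags = generate_tags(simplified_tokens, unified, gold_alignment, layers)

    return SynthPair(
        pair_id=pair_id,
        sentence=sentence,
        anon_sentence=anon_sentence,
        anon_map=anon_map,
        dep_tree=dep_tree,
        statements=statements,
        unified=unified,
        entity_table=entity_table,
        simplified_indices=simplified_indices,
        simplified_tokens=simplified_tokens,
        node_sequence=node_sequence,
        gold_alignment=gold_alignment,
        gold_tags=gold_tags,
        L=layers.L,
        flags=flags,
    )


def generate_corpus(cfg: GenConfig) -> list[SynthPair]:
    """Deterministic corpus of n_pairs fully annotated pairs."""
    vocab = cfg.vocab()
    if not any(vocab.values()):
        raise ValueError("entity vocabulary is empty")
    rng = random.Random(cfg.seed)
    return [_generate_pair(rng, cfg, vocab, i) for i in range(cfg.n_pairs)]


# ---------------------------------------------------------------------------
# random trees for round-trip property tests

_RANDOM_FUNCS = (("complex", 2), ("complex", 3), ("cat", 1), ("deg", 1),
                 ("tloc", 1), ("kin", 1))


def random_tree(rng: random.Random, max_depth: int = 4) -> BELTree:
    """Random normalized BEL tree (depth <= max_depth, arity <= 3)."""
    counter = [0]

    def make_entity() -> BELNode:
        counter[0] += 1
        etype = rng.choice(["gene", "gene", "chem", "bp", "dis"])
        return BELNode("entity", f"{_NAMESPACE[etype]}:E{counter[0]}",
                       entity_type=etype)

    def make_term(depth: int) -> BELNode:
        if depth >= max_depth - 1 or rng.random() < 0.45:
            return make_entity()
        if rng.random() < 0.2:
            # elevated modification function over an entity
            name = rng.choice(["pmod", "sub", "trunc"])
            params = [BELNode("parameter", "P"), BELNode("parameter", "S"),
                      BELNode("parameter", str(rng.randrange(1, 999)))]
            return BELNode("function", name, [make_entity()] + params[: rng.randrange(1, 4)])
        name, arity = rng.choice(_RANDOM_FUNCS)
        return BELNode("function", name, [make_term(depth + 1) for _ in range(arity)])

    relation = rng.choice(["increases", "decreases", "directlyIncreases",
                           "directlyDecreases"])
    root = BELNode("relation", relation, [make_term(1), make_term(1)])
    return BELTree(root)


# ---------------------------------------------------------------------------
# fixture bundle I/O


def write_fixture_bundle(corpus: list[SynthPair], directory) -> None:
    """Emit statements TSV, CoNLL-U parses, Pharaoh alignments and tag files."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "statements.tsv", "w", encoding="utf-8") as fh:
        for pair in corpus:
            for tree in pair.statements:
                fh.write(f"{pair.pair_id}\t{render_statement(tree)}\n")

    write_conllu(
        [
            ConlluSentence(p.pair_id, [t.surface for t in p.sentence.tokens],
                           p.dep_tree)
            for p in corpus
        ],
        directory / "parses.conllu",
    )

    with open(directory / "source.txt", "w", encoding="utf-8") as fs, \
            open(directory / "target.txt", "w", encoding="utf-8") as ft:
        for p in corpus:
            fs.write(" ".join(t.surface for t in p.simplified_tokens) + "\n")
            ft.write(" ".join(p.node_sequence) + "\n")

    with open(directory / "alignments.tsv", "w", encoding="utf-8") as fh:
        for p in corpus:
            fh.write(f"{p.pair_id}\t{format_pharaoh(p.gold_alignment)}\n")

    from .hier_tagging import write_tag_file

    write_tag_file(
        [(p.simplified_tokens, p.gold_tags) for p in corpus],
        directory / "tags.conll",
    )

    with open(directory / "entities.tsv", "w", encoding="utf-8") as fh:
        for p in corpus:
            for placeholder, (ns, ident, etype) in sorted(p.entity_table.items()):
                fh.write(f"{p.pair_id}\t{placeholder}\t{ns}\t{ident}\t{etype}\n")
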