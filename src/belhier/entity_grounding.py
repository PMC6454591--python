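"""Ground statement entities in the sentence text.

Three cascaded passes mirror how a practitioner maximizes entity recall:

1. an optional NER hook supplying precomputed mentions (the package never
   shells out to external taggers — it consumes their output files);
2. identifier renormalization — gene/protein identifiers pass through
   (Entrez/HGNC/MGI are treated as consistent), chemicals are mapped to
   CHEBI via a user-supplied table, OMIM-linked diseases are discarded;
3. dictionary search — the contiguous token window with minimal normalized
   edit distance to any symbol/synonym of the entity, accepted under a
   distance threshold.

Edit distances are character-level on lowercased strings (via edlib),
normalized by the longer string's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import edlib

from .bel_core import BELTree
from .errors import FormatError
from .text_preproc import AnnotatedSentence, Token

#: default acceptance threshold on normalized edit distance
DEFAULT_THRESHOLD = 0.2
#: default maximal window width in tokens
DEFAULT_MAX_SPAN = 6

ABSENT = None  # mention span value for entities not found in the sentence


@dataclass
class DictionaryEntry:
    namespace: str
    identifier: str
    names: list[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.namespace}:{self.identifier}"


@dataclass
class Dictionary:
    entries: dict[str, DictionaryEntry] = field(default_factory=dict)

    def add(self, namespace: str, identifier: str, name: str) -> None:
        key = f"{namespace}:{identifier}"
        entry = self.entries.setdefault(key, DictionaryEntry(namespace, identifier))
        if name not in entry.names:
            entry.names.append(name)

    def get(self, key: str) -> DictionaryEntry | None:
        return self.entries.get(key)

    def __len__(self) -> int:
        return len(self.entries)


def load_dictionary_tsv(path) -> Dictionary:
    """Read ``namespace<TAB>identifier<TAB>name`` rows (one name per row)."""
    d = Dictionary()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("dictionary row needs 3 tab-separated fields",
                                  line=lineno)
            d.add(parts[0], parts[1], parts[2])
    return d


class Renormalized(NamedTuple):
    identifier: str | None
    discarded: bool
    reason: str | None


def renormalize_identifier(
    identifier: str,
    source_db: str,
    entity_type: str,
    chem_to_chebi: dict[str, str] | None = None,
) -> Renormalized:
    """Map an externally recognized identifier into the task's namespaces.

    Genes/proteins pass through unchanged; chemicals need a name→CHEBI table;
    OMIM-linked diseases are discarded (no OMIM→MESH conversion exists).
    """
    db = source_db.upper()
    if entity_type == "gene" or db in ("ENTREZ", "EGID", "HGNC", "MGI"):
        return Renormalized(identifier, False, None)
    if entity_type == "chem":
        if db == "CHEBI":
            return Renormalized(identifier, False, None)
        mapped = (chem_to_chebi or {}).get(identifier)
        if mapped is None:
            return Renormalized(None, True, f"no CHEBI mapping for '{identifier}'")
        return Renormalized(mapped, False, None)
    if entity_type == "dis":
        if db == "OMIM":
            return Renormalized(None, True, "OMIM-linked disease identifiers are discarded")
        return Renormalized(identifier, False, None)
    return Renormalized(identifier, False, None)


@dataclass
class GroundingResult:
    entity_key: str  # namespace:identifier as it appears in the statement
    span: tuple[int, int] | None  # token interval [start, end) or ABSENT
    method: str | None  # "ner" | "dictionary" | None
    distance: float | None = None

    @property
    def absent(self) -> bool:
        return self.span is ABSENT


def normalized_edit_distance(a: str, b: str) -> float:
    """Character-level edit distance on lowercased strings, in [0, 1]."""
    a, b = a.lower(), b.lower()
    if not a and not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def _surfaces(tokens) -> list[str]:
    return [t.surface if isinstance(t, Token) else str(t) for t in tokens]


def dictionary_search(
    tokens,
    entry: DictionaryEntry,
    max_span: int = DEFAULT_MAX_SPAN,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[tuple[int, int], float] | None:
    """Best contiguous token window for *entry*, or ABSENT.

    Minimizes normalized edit distance between the space-joined window and
    any entry name; ties break toward the longer window, then leftmost.
    Returns ``((start, end), distance)`` when distance <= threshold.
    """
    surfaces = _surfaces(tokens)
    if not surfaces or not entry.names:
        return ABSENT
    best: tuple[float, int, int] | None = None  # (distance, -width, start)
    best_span: tuple[int, int] | None = None
    for start in range(len(surfaces)):
        for width in range(1, min(max_span, len(surfaces) - start) + 1):
            window = " ".join(surfaces[start : start + width])
            dist = min(normalized_edit_distance(window, name) for name in entry.names)
            key = (dist, -width, start)
            if best is None or key < best:
                best = key
                best_span = (start, start + width)
    assert best is not None and best_span is not None
    if best[0] <= threshold:
        return best_span, best[0]
    return ABSENT


@dataclass
class NerMention:
    """A precomputed mention from an external NER tool's output file."""

    start: int  # character offsets into the raw sentence
    end: int
    entity_type: str
    source_db: str
    identifier: str


def load_ner_mentions_tsv(path) -> dict[str, list[NerMention]]:
    """Read ``sentence_id, start, end, type, db, identifier`` TSV rows."""
    mentions: dict[str, list[NerMention]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError("NER mention row needs 6 fields", line=lineno)
            sid, start, end, etype, db, ident = parts[:6]
            mentions.setdefault(sid, []).append(
                NerMention(int(start), int(end), etype, db, ident)
            )
    return mentions


def _char_span_to_tokens(sentence: AnnotatedSentence, start: int, end: int):
    covered = [i for i, t in enumerate(sentence.tokens)
               if t.start < end and t.end > start]
    if not covered:
        return None
    return covered[0], covered[-1] + 1


NerHook = Callable[[AnnotatedSentence], list[NerMention]]


def ground_statement_entities(
    sentence: AnnotatedSentence,
    statement: BELTree,
    dictionary: Dictionary,
    ner_hook: NerHook | None = None,
    chem_to_chebi: dict[str, str] | None = None,
    max_span: int = DEFAULT_MAX_SPAN,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[GroundingResult]:
    """One GroundingResult per distinct entity leaf of the statement.

    ABSENT is a value, not an error; pairs with ABSENT entities are filtered
    downstream.
    """
    seen: list[str] = []
    for leaf in statement.entity_leaves():
        if leaf.label not in seen:
            seen.append(leaf.label)

    ner_mentions = list(ner_hook(sentence)) if ner_hook else []
    resolved: dict[str, tuple[int, int]] = {}
    for m in ner_mentions:
        renorm = renormalize_identifier(m.identifier, m.source_db, m.entity_type,
                                        chem_to_chebi)
        if renorm.discarded or renorm.identifier is None:
            continue
        span = _char_span_to_tokens(sentence, m.start, m.end)
        if span is None:
            continue
        resolved.setdefault(renorm.identifier, span)

    results: list[GroundingResult] = []
    for key in seen:
        if key in resolved:
            results.append(GroundingResult(key, resolved[key], "ner", 0.0))
            continue
        entry = dictionary.get(key)
        if entry is not None:
            hit = dictionary_search(sentence.tokens, entry, max_span, threshold)
            if hit is not ABSENT:
                span, dist = hit
                results.append(GroundingResult(key, span, "dictionary", dist))
                continue
        results.append(GroundingResult(key, ABSENT, None, None))
    return results
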