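"""Sentence tokenization and entity anonymization.

Tokenization is deliberately minimal — whitespace splitting plus the three
rules that matter for BEL extraction from biomedical text:

1. a comma followed by a space ends a token, while a comma followed by a
   letter or digit usually sits inside a biomedical name and stays attached;
2. hyphenated compounds ending in "ed"/"ing" are split at the hyphen
   (``progesterone-induced`` → ``progesterone - induced``), because the
   participle frequently carries the causal relation;
3. residue abbreviations fused with positions are split
   (``Ser727`` → ``Ser 727``), exposing pmod() parameters.

Anonymization replaces grounded entity mentions with typed, densely numbered
placeholders (GENE_1, CHEM_1, BP_1, DIS_1 ...) and keeps an inverse mapping
so the original token sequence is recoverable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

from .bel_core import PLACEHOLDER_PREFIX

AMINO_THREE = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}
AMINO_ONE = set("ACDEFGHIKLMNPQRSTVWY")

_RESIDUE_RE = re.compile(r"^([A-Za-z]+)(\d+)$")
_CHUNK_RE = re.compile(r"\S+")


@dataclass
class Token:
    surface: str
    start: int
    end: int
    stem: str = ""
    is_placeholder: bool = False


@dataclass
class Mention:
    """Entity mention over a token span [start_token, end_token)."""

    start_token: int
    end_token: int
    entity_type: str
    entity_id: str  # namespace:identifier
    placeholder: str | None = None


@dataclass
class AnnotatedSentence:
    sentence_id: str
    raw_text: str
    tokens: list[Token] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)


_SUFFIXES = (
    "ational", "ization", "izations", "ations", "ingly", "ation", "ments",
    "ness", "ment", "ings", "ing", "edly", "ies", "ed", "es", "ly", "s",
)
_SUFFIXES = tuple(sorted(_SUFFIXES, key=len, reverse=True))


def stem(word: str) -> str:
    """Deterministic suffix-stripping stem (lowercased)."""
    w = word.lower()
    for suffix in _SUFFIXES:
        if w.endswith(suffix) and len(w) - len(suffix) >= 3:
            return w[: len(w) - len(suffix)]
    return w


def _is_residue(piece: str) -> re.Match | None:
    m = _RESIDUE_RE.match(piece)
    if m and (m.group(1) in AMINO_THREE or m.group(1) in AMINO_ONE):
        return m
    return None


def _split_chunk(chunk: str, offset: int) -> list[tuple[str, int, int]]:
    parts: list[tuple[str, int, int]] = []

    # rule 1: comma before whitespace == chunk-trailing comma -> own token;
    # commas inside the chunk (followed by a letter/digit) stay attached
    body = chunk
    trailing: list[tuple[str, int, int]] = []
    while body.endswith(","):
        trailing.insert(0, (",", offset + len(body) - 1, offset + len(body)))
        body = body[:-1]
    if not body:
        return trailing

    # rule 2: hyphenated compound ending in ed/ing -> split at every hyphen,
    # hyphens kept as their own tokens so offsets stay recoverable
    segments: list[tuple[str, int]]
    if "-" in body and body.lower().rstrip(".").split("-")[-1].endswith(("ed", "ing")):
        segments = []
        pos = 0
        for seg in body.split("-"):
            if seg:
                segments.append((seg, pos))
            pos += len(seg)
            if pos < len(body):
                segments.append(("-", pos))
                pos += 1
    else:
        segments = [(body, 0)]

    # rule 3: amino-acid code fused with a position number
    for seg, rel in segments:
        abs_start = offset + rel
        m = _is_residue(seg)
        if m:
            letters, digits = m.group(1), m.group(2)
            parts.append((letters, abs_start, abs_start + len(letters)))
            parts.append((digits, abs_start + len(letters), abs_start + len(seg)))
        else:
            parts.append((seg, abs_start, abs_start + len(seg)))
    return parts + trailing


def tokenize(text: str) -> list[Token]:
    """Tokenize one sentence; offsets are 0-based half-open into *text*."""
    tokens: list[Token] = []
    for m in _CHUNK_RE.finditer(text):
        for surface, start, end in _split_chunk(m.group(0), m.start()):
            tokens.append(Token(surface, start, end, stem=stem(surface)))
    return tokens


def make_sentence(sentence_id: str, text: str) -> AnnotatedSentence:
    return AnnotatedSentence(sentence_id, text, tokenize(text))


# ---------------------------------------------------------------------------
# anonymization


@dataclass
class AnonymizationMap:
    """Per placeholder-token index, the original tokens it replaced."""

    original: dict[int, list[Token]] = field(default_factory=dict)


def anonymize(sentence: AnnotatedSentence) -> tuple[AnnotatedSentence, AnonymizationMap]:
    """Collapse each mention span to a single typed placeholder token.

    Repeated mentions of the same entity reuse the same placeholder;
    numbering is dense per type in order of first occurrence.
    """
    mentions = sorted(sentence.mentions, key=lambda m: (m.start_token, m.end_token))
    for prev, cur in zip(mentions, mentions[1:]):
        if cur.start_token < prev.end_token:
            raise ValueError(
                f"overlapping mentions at tokens {prev.start_token}-{prev.end_token}"
                f" and {cur.start_token}-{cur.end_token}"
            )

    counters: dict[str, int] = {}
    assigned: dict[str, str] = {}
    for m in mentions:
        if m.entity_id not in assigned:
            counters[m.entity_type] = counters.get(m.entity_type, 0) + 1
            prefix = PLACEHOLDER_PREFIX[m.entity_type]
            assigned[m.entity_id] = f"{prefix}_{counters[m.entity_type]}"

    new_tokens: list[Token] = []
    new_mentions: list[Mention] = []
    amap = AnonymizationMap()
    idx = 0
    mention_iter = iter(mentions)
    current = next(mention_iter, None)
    while idx < len(sentence.tokens):
        if current is not None and idx == current.start_token:
            span = sentence.tokens[current.start_token : current.end_token]
            placeholder = assigned[current.entity_id]
            new_idx = len(new_tokens)
            new_tokens.append(
                Token(placeholder, span[0].start, span[-1].end,
                      stem=placeholder, is_placeholder=True)
            )
            amap.original[new_idx] = list(span)
            new_mentions.append(
                Mention(new_idx, new_idx + 1, current.entity_type,
                        current.entity_id, placeholder)
            )
            idx = current.end_token
            current = next(mention_iter, None)
        else:
            new_tokens.append(replace(sentence.tokens[idx]))
            idx += 1
    return (
        AnnotatedSentence(sentence.sentence_id, sentence.raw_text, new_tokens, new_mentions),
        amap,
    )


def deanonymize(sentence: AnnotatedSentence, amap: AnonymizationMap) -> list[Token]:
    """Restore the original token sequence of an anonymized sentence."""
    out: list[Token] = []
    for idx, token in enumerate(sentence.tokens):
        if token.is_placeholder and idx in amap.original:
            out.extend(amap.original[idx])
        else:
            out.append(token)
    return out


# ---------------------------------------------------------------------------
# JSONL I/O


def write_jsonl(sentences: list[AnnotatedSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps(sentence_to_dict(s)) + "\n")


def read_jsonl(path) -> list[AnnotatedSentence]:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                sentences.append(sentence_from_dict(json.loads(line)))
    return sentences


def sentence_to_dict(s: AnnotatedSentence) -> dict:
    return {
        "sentence_id": s.sentence_id,
        "raw_text": s.raw_text,
        "tokens": [
            {"surface": t.surface, "start": t.start, "end": t.end,
             "stem": t.stem, "is_placeholder": t.is_placeholder}
            for t in s.tokens
        ],
        "mentions": [
            {"start_token": m.start_token, "end_token": m.end_token,
             "entity_type": m.entity_type, "entity_id": m.entity_id,
             "placeholder": m.placeholder}
            for m in s.mentions
        ],
    }


def sentence_from_dict(d: dict) -> AnnotatedSentence:
    return AnnotatedSentence(
        d["sentence_id"],
        d["raw_text"],
        [Token(**t) for t in d["tokens"]],
        [Mention(**m) for m in d["mentions"]],
    )
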