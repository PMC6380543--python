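"""Concept extraction: note text -> CUI codes with negation flags.

A deliberately transparent stand-in for a full clinical NLP engine: sentence
splitting on terminal punctuation and newlines, tokenization into
alphanumeric runs, case-insensitive greedy leftmost-longest dictionary
matching of lexicon variants, and NegEx-style rule negation (a trigger
phrase within a bounded window of tokens preceding the mention, in the same
sentence, with no intervening contrast conjunction). A negated mention of
CUI ``Cxxxxxxx`` contributes the separate feature code ``Cxxxxxxx_neg``;
the downstream model consumes only presence/absence of these codes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus_io import Lexicon, Note

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_TERMINAL = {".", "!", "?"}

#: default NegEx-style negation triggers; multi-word triggers are token tuples
DEFAULT_TRIGGERS: tuple[tuple[str, ...], ...] = (
    ("no",),
    ("not",),
    ("denies",),
    ("denied",),
    ("without",),
    ("negative", "for"),
)
#: conjunctions that terminate a negation scope
DEFAULT_CONJUNCTIONS: frozenset[str] = frozenset({"but", "however"})
DEFAULT_WINDOW = 6


@dataclass
class ExtractionConfig:
    """Tunable rules of the extractor.

    window is the number of tokens preceding a mention that is searched for
    a negation trigger. stem enables naive plural folding ("attempts" ->
    "attempt") on both lexicon variants and note tokens; off by default.
    """

    triggers: tuple[tuple[str, ...], ...] = DEFAULT_TRIGGERS
    conjunctions: frozenset[str] = DEFAULT_CONJUNCTIONS
    window: int = DEFAULT_WINDOW
    stem: bool = False


@dataclass
class ConceptMention:
    """One lexicon match in a note, as character offsets into the note text."""

    cui: str
    start: int
    end: int
    matched_text: str
    negated: bool = False


@dataclass
class NoteCuiSet:
    """The set of feature codes extracted from one note."""

    note_id: str
    patient_id: str
    feature_codes: set[str] = field(default_factory=set)


def split_sentences(text: str) -> list[tuple[str, int]]:
    """Split text into (sentence, start offset) pairs.

    A sentence ends after '.', '!' or '?' followed by whitespace (or end of
    text), or at a newline. Offsets index the original text.
    """
    sentences: list[tuple[str, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            seg = text[start:i]
            if seg.strip():
                sentences.append((seg, start))
            start = i + 1
        elif ch in _TERMINAL and (i + 1 == n or text[i + 1].isspace()):
            seg = text[start : i + 1]
            if seg.strip():
                sentences.append((seg, start))
            start = i + 1
        i += 1
    tail = text[start:]
    if tail.strip():
        sentences.append((tail, start))
    return sentences


def normalize_tokens(sentence: str) -> list[tuple[str, int, int]]:
    """Lowercased alphanumeric tokens with (start, end) offsets in sentence."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence)]


def _stem(token: str) -> str:
    # naive plural folding only; adequate for dictionary presence matching
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def _variant_index(
    lexicon: Lexicon, config: ExtractionConfig
) -> dict[tuple[str, ...], list[str]]:
    """Map variant token-tuples to the CUIs they denote."""
    index: dict[tuple[str, ...], list[str]] = {}
    for cui in sorted(lexicon.entries):
        for variant in lexicon.entries[cui].variants:
            key = tuple(t for t, _, _ in normalize_tokens(variant))
            if config.stem:
                key = tuple(_stem(t) for t in key)
            if not key:
                continue
            cuis = index.setdefault(key, [])
            if cui not in cuis:
                cuis.append(cui)
    return index


def match_concepts(
    tokens: list[tuple[str, int, int]],
    lexicon: Lexicon,
    config: ExtractionConfig | None = None,
    sentence: str = "",
) -> list[ConceptMention]:
    """Greedy leftmost-longest non-overlapping match of lexicon variants.

    Offsets in the returned mentions are relative to the tokenized sentence;
    ``matched_text`` is the covered span of ``sentence`` when provided.
    Returns mentions with ``negated=False``; pair with :func:`detect_negation`.
    """
    config = config or ExtractionConfig()
    index = _variant_index(lexicon, config)
    if not index:
        return []
    max_len = max(len(k) for k in index)
    words = [_stem(t) if config.stem else t for t, _, _ in tokens]
    mentions: list[ConceptMention] = []
    i = 0
    while i < len(words):
        matched = False
        for length in range(min(max_len, len(words) - i), 0, -1):
            key = tuple(words[i : i + length])
            if key in index:
                start = tokens[i][1]
                end = tokens[i + length - 1][2]
                for cui in index[key]:
                    mentions.append(
                        ConceptMention(
                            cui=cui,
                            start=start,
                            end=end,
                            matched_text=sentence[start:end] if sentence else " ".join(key),
                        )
                    )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def detect_negation(
    mentions: list[ConceptMention],
    tokens: list[tuple[str, int, int]],
    config: ExtractionConfig | None = None,
) -> list[ConceptMention]:
    """Set negated flags: trigger within the preceding window, no intervening
    contrast conjunction, same sentence."""
    config = config or ExtractionConfig()
    words = [t for t, _, _ in tokens]
    # token index at which each mention starts
    start_of = {tok_start: idx for idx, (_, tok_start, _) in enumerate(tokens)}
    out: list[ConceptMention] = []
    for m in mentions:
        i = start_of.get(m.start)
        negated = False
        if i is not None:
            lo = max(0, i - config.window)
            for j in range(lo, i):
                for trig in config.triggers:
                    end_j = j + len(trig)
                    if end_j <= i and tuple(words[j:end_j]) == trig:
                        # scope runs from the trigger's last token to the mention
                        blocked = any(
                            words[k] in config.conjunctions for k in range(end_j, i)
                        )
                        if not blocked:
                            negated = True
                if negated:
                    break
        out.append(
            ConceptMention(
                cui=m.cui, start=m.start, end=m.end,
                matched_text=m.matched_text, negated=negated,
            )
        )
    return out


def extract_mentions(
    note: Note, lexicon: Lexicon, config: ExtractionConfig | None = None
) -> list[ConceptMention]:
    """All mentions of a note with offsets into the full note text."""
    config = config or ExtractionConfig()
    out: list[ConceptMention] = []
    for sentence, offset in split_sentences(note.text):
        tokens = normalize_tokens(sentence)
        mentions = match_concepts(tokens, lexicon, config, sentence=sentence)
        for m in detect_negation(mentions, tokens, config):
            out.append(
                ConceptMention(
                    cui=m.cui,
                    start=m.start + offset,
                    end=m.end + offset,
                    matched_text=m.matched_text,
                    negated=m.negated,
                )
            )
    return out


def extract_note_cuis(
    note: Note, lexicon: Lexicon, config: ExtractionConfig | None = None
) -> NoteCuiSet:
    """split -> tokenize -> match -> negate over all sentences; set semantics."""
    config = config or ExtractionConfig()
    codes: set[str] = set()
    for sentence, _offset in split_sentences(note.text):
        tokens = normalize_tokens(sentence)
        mentions = match_concepts(tokens, lexicon, config, sentence=sentence)
        for m in detect_negation(mentions, tokens, config):
            codes.add(m.cui + "_neg" if m.negated else m.cui)
    return NoteCuiSet(note_id=note.note_id, patient_id=note.patient_id, feature_codes=codes)


def extract_corpus(corpus, lexicon: Lexicon, config: ExtractionConfig | None = None) -> list[NoteCuiSet]:
    """Extract every note of a corpus, in corpus note order."""
    config = config or ExtractionConfig()
    return [extract_note_cuis(n, lexicon, config) for n in corpus.notes]
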