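"""Extraction tests, including equivalence against an independent
brute-force matcher that enumerates every variant placement and applies the
same leftmost-longest and negation-scope rules via a different algorithm."""

import datetime as dt
import re

import numpy as np
import pytest

from suicidality_pipeline.corpus_io import Lexicon, LexiconEntry, Note
from suicidality_pipeline.extraction import (
    ExtractionConfig,
    detect_negation,
    extract_mentions,
    extract_note_cuis,
    match_concepts,
    normalize_tokens,
    split_sentences,
)

# ---------------------------------------------------------------------------
# independent oracle

_TRIGGERS = [("no",), ("not",), ("denies",), ("denied",), ("without",), ("negative", "for")]
_CONJ = {"but", "however"}
_WINDOW = 6


def oracle_sentences(text):
    """Regex-based splitter using the same boundary rule set."""
    bounds = [m.end() for m in re.finditer(r"[.!?](?=\s|$)|\n", text)]
    out, start = [], 0
    for b in bounds:
        end = b - 1 if text[b - 1] == "\n" else b
        seg = text[start:end]
        if seg.strip():
            out.append((seg, start))
        start = b
    tail = text[start:]
    if tail.strip():
        out.append((tail, start))
    return out


def oracle_extract(text, lexicon):
    """Enumerate every variant at every token position, then resolve
    overlaps by repeatedly taking the earliest (then longest) candidate."""
    codes = set()
    for sent, _ in oracle_sentences(text):
        toks = [(m.group(0).lower(), m.start(), m.end()) for m in re.finditer(r"[A-Za-z0-9]+", sent)]
        words = [t for t, _, _ in toks]
        variant_map = {}
        for cui in lexicon.entries:
            for v in lexicon.entries[cui].variants:
                key = tuple(w.lower() for w in re.findall(r"[A-Za-z0-9]+", v))
                if key:
                    variant_map.setdefault(key, set()).add(cui)
        candidates = []  # (start_tok, length, cuis)
        for key, cuis in variant_map.items():
            for i in range(len(words) - len(key) + 1):
                if tuple(words[i : i + len(key)]) == key:
                    candidates.append((i, len(key), cuis))
        chosen = []
        while candidates:
            first = min(c[0] for c in candidates)
            at_first = [c for c in candidates if c[0] == first]
            best = max(at_first, key=lambda c: c[1])
            chosen.append(best)
            lo, hi = best[0], best[0] + best[1]
            candidates = [c for c in candidates if c[0] + c[1] <= lo or c[0] >= hi]
        # negation: any trigger placement in the window before the mention
        trigger_spots = []
        for trig in _TRIGGERS:
            for i in range(len(words) - len(trig) + 1):
                if tuple(words[i : i + len(trig)]) == trig:
                    trigger_spots.append((i, i + len(trig)))
        for start_tok, _length, cuis in chosen:
            negated = any(
                t_start >= start_tok - _WINDOW
                and t_end <= start_tok
                and not any(w in _CONJ for w in words[t_end:start_tok])
                for t_start, t_end in trigger_spots
            )
            for cui in cuis:
                codes.add(cui + "_neg" if negated else cui)
    return codes


def lex(*entries):
    return Lexicon(
        entries={
            cui: LexiconEntry(cui, variants[0], list(variants))
            for cui, variants in entries
        }
    )


SMALL_LEX = lex(
    ("C0000001", ("suicide attempt", "suicide attempts")),
    ("C0000002", ("suicide",)),
    ("C0000003", ("pain",)),
    ("C0000004", ("suicidal thoughts", "thoughts of suicide")),
    ("C0000005", ("severe depression",)),
)


def note(text):
    return Note("n1", "p1", dt.date(2015, 1, 1), text)


class TestSplitSentences:
    def test_two_terminals(self):
        sents = split_sentences("He is sad. No suicide attempts.")
        assert [s for s, _ in sents] == ["He is sad.", " No suicide attempts."]

    def test_empty(self):
        assert split_sentences("") == []

    def test_offsets_map_back(self):
        text = "First one. Second!\nThird line"
        for sent, off in split_sentences(text):
            assert text[off : off + len(sent)] == sent

    def test_abbreviation_matches_oracle(self):
        text = "Dr. Smith saw pt. Patient stable."
        assert [(s.strip(), o) for s, o in split_sentences(text)] == [
            (s.strip(), o) for s, o in oracle_sentences(text)
        ]


class TestNormalizeTokens:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("No suicide attempts.", ["no", "suicide", "attempts"]),
            ("", []),
            ("ADHD/PTSD", ["adhd", "ptsd"]),
        ],
    )
    def test_examples(self, text, expected):
        assert [t for t, _, _ in normalize_tokens(text)] == expected

    def test_offsets_reference_original(self):
        text = "Pt denies PAIN today"
        for tok, s, e in normalize_tokens(text):
            assert text[s:e].lower() == tok


class TestMatchConcepts:
    def test_multiword_match(self):
        sent = "thoughts of suicide today"
        toks = normalize_tokens(sent)
        mentions = match_concepts(toks, SMALL_LEX, sentence=sent)
        assert [m.cui for m in mentions] == ["C0000004"]
        assert mentions[0].matched_text == "thoughts of suicide"

    def test_no_match(self):
        toks = normalize_tokens("nothing relevant here")
        assert match_concepts(toks, SMALL_LEX) == []

    def test_leftmost_longest_beats_shorter_overlap(self):
        sent = "suicide attempt noted"
        toks = normalize_tokens(sent)
        mentions = match_concepts(toks, SMALL_LEX, sentence=sent)
        assert [m.cui for m in mentions] == ["C0000001"]


class TestDetectNegation:
    def test_no_suicide_attempts(self):
        sent = "no suicide attempts"
        toks = normalize_tokens(sent)
        [m] = detect_negation(match_concepts(toks, SMALL_LEX, sentence=sent), toks)
        assert m.cui == "C0000001" and m.negated

    def test_no_trigger(self):
        sent = "suicide attempts last year"
        toks = normalize_tokens(sent)
        [m] = detect_negation(match_concepts(toks, SMALL_LEX, sentence=sent), toks)
        assert not m.negated

    def test_conjunction_blocks_scope(self):
        sent = "denies pain but reports suicidal thoughts"
        toks = normalize_tokens(sent)
        mentions = detect_negation(match_concepts(toks, SMALL_LEX, sentence=sent), toks)
        flags = {m.cui: m.negated for m in mentions}
        assert flags == {"C0000003": True, "C0000004": False}

    def test_window_limit(self):
        sent = "no one two three four five six pain"
        toks = normalize_tokens(sent)
        [m] = detect_negation(match_concepts(toks, SMALL_LEX, sentence=sent), toks)
        assert not m.negated  # trigger is 7 tokens back, outside the window


class TestExtractNoteCuis:
    def test_composed_example(self):
        s = extract_note_cuis(
            note("No suicide attempts. Reports severe depression."), SMALL_LEX
        )
        assert s.feature_codes == {"C0000001_neg", "C0000005"}

    def test_empty_note(self):
        assert extract_note_cuis(note(""), SMALL_LEX).feature_codes == set()

    def test_set_semantics(self):
        text = " ".join(["pain."] * 5)
        assert extract_note_cuis(note(text), SMALL_LEX).feature_codes == {"C0000003"}

    def test_purity(self):
        n = note("No suicide attempts but pain persists.")
        assert (
            extract_note_cuis(n, SMALL_LEX).feature_codes
            == extract_note_cuis(n, SMALL_LEX).feature_codes
        )

    def test_mention_offsets_round_trip(self):
        n = note("Denies pain today.\nReports thoughts of suicide. No pain!")
        for m in extract_mentions(n, SMALL_LEX):
            assert n.text[m.start : m.end] == m.matched_text


VOCAB = [
    "suicide", "attempt", "attempts", "pain", "thoughts", "of", "suicidal",
    "severe", "depression", "no", "not", "denies", "without", "negative",
    "for", "but", "however", "patient", "reports", "today", "stable",
    "family", "school", "mood",
]


def random_note_text(rng):
    words = []
    for _ in range(rng.integers(3, 30)):
        words.append(VOCAB[rng.integers(len(VOCAB))])
        if rng.random() < 0.12:
            words[-1] += rng.choice([".", "!", "?"])
        if rng.random() < 0.05:
            words[-1] += "\n"
    return " ".join(words)


def random_lexicon(rng):
    entries = {}
    n = rng.integers(3, 21)
    for i in range(n):
        cui = f"C{9000000 + i}"
        variants = []
        for _ in range(rng.integers(1, 4)):
            length = int(rng.integers(1, 4))
            variants.append(" ".join(VOCAB[rng.integers(len(VOCAB))] for _ in range(length)))
        entries[cui] = LexiconEntry(cui, variants[0], variants)
    return Lexicon(entries=entries)


class TestOracleEquivalence:
    def test_random_notes_match_brute_force(self):
        """Extraction equals the brute-force placement enumerator on random
        short notes and random small lexicons."""
        rng = np.random.default_rng(12345)
        for trial in range(60):
            lexicon = random_lexicon(rng)
            for _ in range(4):
                text = random_note_text(rng)
                got = extract_note_cuis(note(text), lexicon).feature_codes
                want = oracle_extract(text, lexicon)
                assert got == want, f"trial {trial}: {text!r}"
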