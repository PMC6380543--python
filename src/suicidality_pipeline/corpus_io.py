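"""Corpus, lexicon and curated-term I/O.

The corpus is a JSONL file holding two record kinds distinguished by a
``"kind"`` field: ``patient`` records carry the binary past-year
suicide-attempt label obtained from a self-report survey, and ``note``
records carry free-text clinical notes keyed to a patient. Lexicons map
UMLS-style Concept Unique Identifiers (CUIs, ``C`` + 7 digits, treated as
opaque codes) to surface-term variants; the curated lexicon is a
clinician-style list of risk and protective terms.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

CUI_PATTERN = re.compile(r"^C\d{7}$")
#: feature codes are a CUI or a CUI with the negation suffix
FEATURE_CODE_PATTERN = re.compile(r"^C\d{7}(_neg)?$")

CATEGORIES = ("risk", "protective")


class CorpusFormatError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a structural invariant (orphan note, bad id...)."""


@dataclass
class Patient:
    """One surveyed adolescent with a binary past-year attempt outcome."""

    patient_id: str
    attempt_label: int
    demographics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.attempt_label not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: attempt_label must be 0 or 1, "
                f"got {self.attempt_label!r}"
            )


@dataclass
class Note:
    """One clinical note from the year preceding the index admission."""

    note_id: str
    patient_id: str
    timestamp: dt.date
    text: str


@dataclass
class Corpus:
    """Patients plus their notes; every note must resolve to a patient."""

    patients: dict[str, Patient] = field(default_factory=dict)
    notes: list[Note] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_notes: set[str] = set()
        for note in self.notes:
            if note.note_id in seen_notes:
                raise ValidationError(f"duplicate note_id {note.note_id!r}")
            seen_notes.add(note.note_id)
            if note.patient_id not in self.patients:
                raise ValidationError(
                    f"orphan note {note.note_id!r}: unknown patient "
                    f"{note.patient_id!r}"
                )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_notes(self) -> int:
        return len(self.notes)

    def labels(self) -> dict[str, int]:
        """patient_id -> attempt label."""
        return {pid: p.attempt_label for pid, p in self.patients.items()}

    def notes_by_patient(self) -> dict[str, list[Note]]:
        """All notes grouped per patient (patients with no notes included)."""
        out: dict[str, list[Note]] = {pid: [] for pid in self.patients}
        for note in self.notes:
            out[note.patient_id].append(note)
        return out

    def note_index(self) -> dict[str, Note]:
        return {n.note_id: n for n in self.notes}


@dataclass
class LexiconEntry:
    cui: str
    preferred_term: str
    variants: list[str]


@dataclass
class Lexicon:
    """CUI code -> preferred term and surface variants.

    Case is preserved on read; all downstream matching is case-insensitive.
    """

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cui, entry in self.entries.items():
            if not CUI_PATTERN.match(cui):
                raise ValidationError(f"invalid CUI code {cui!r}")
            if not entry.variants:
                raise ValidationError(f"CUI {cui!r} has no variants")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, cui: str) -> bool:
        return cui in self.entries


@dataclass
class CuratedTerm:
    surface_term: str
    category: str  # "risk" or "protective"


@dataclass
class CuratedLexicon:
    """Clinician-style list of risk and protective surface terms."""

    terms: list[CuratedTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.terms:
            if not t.surface_term:
                raise ValidationError("empty curated surface_term")
            if t.category not in CATEGORIES:
                raise ValidationError(
                    f"curated term {t.surface_term!r}: unknown category "
                    f"{t.category!r} (expected one of {CATEGORIES})"
                )

    def by_category(self, category: str) -> list[str]:
        return [t.surface_term for t in self.terms if t.category == category]

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# corpus JSONL


def read_corpus(path: str | PathLike) -> Corpus:
    """Read a JSONL corpus (``patient`` and ``note`` records, any order)."""
    patients: dict[str, Patient] = {}
    notes: list[Note] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip("\n")
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: not valid JSON: {exc}") from exc
            kind = rec.get("kind")
            if kind == "patient":
                pid = rec.get("patient_id")
                if pid is None:
                    raise CorpusFormatError(f"line {lineno}: patient record without patient_id")
                if pid in patients:
                    raise ValidationError(f"line {lineno}: duplicate patient_id {pid!r}")
                patients[pid] = Patient(
                    patient_id=pid,
                    attempt_label=rec.get("attempt_label"),
                    demographics=rec.get("demographics") or {},
                )
            elif kind == "note":
                try:
                    ts = dt.date.fromisoformat(rec["timestamp"])
                    notes.append(
                        Note(
                            note_id=rec["note_id"],
                            patient_id=rec["patient_id"],
                            timestamp=ts,
                            text=rec["text"],
                        )
                    )
                except KeyError as exc:
                    raise CorpusFormatError(f"line {lineno}: note record missing field {exc}") from exc
                except ValueError as exc:
                    raise CorpusFormatError(f"line {lineno}: bad timestamp: {exc}") from exc
            else:
                raise CorpusFormatError(f"line {lineno}: unknown record kind {kind!r}")
    corpus = Corpus(patients=patients, notes=notes)
    logger.info("read corpus: %d patients, %d notes", corpus.n_patients, corpus.n_notes)
    return corpus


def write_corpus(corpus: Corpus, path: str | PathLike) -> None:
    """Write a corpus as JSONL; ``read_corpus`` round-trips it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus.patients.values():
            fh.write(
                json.dumps(
                    {
                        "kind": "patient",
                        "patient_id": p.patient_id,
                        "attempt_label": p.attempt_label,
                        "demographics": p.demographics,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
        for n in corpus.notes:
            fh.write(
                json.dumps(
                    {
                        "kind": "note",
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "timestamp": n.timestamp.isoformat(),
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# lexicon TSV (columns: cui, preferred_term, variant — one variant per row)


def _read_tsv(path: str | PathLike, expected: tuple[str, ...]) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            return
        header = header_line.rstrip("\n").split("\t")
        if header != list(expected):
            raise CorpusFormatError(
                f"{Path(path).name}: expected header {list(expected)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(expected):
                raise CorpusFormatError(
                    f"{Path(path).name} line {lineno}: expected "
                    f"{len(expected)} columns, got {len(fields)}"
                )
            yield lineno, fields


def read_lexicon(path: str | PathLike) -> Lexicon:
    """Read a CUI lexicon TSV; variants are grouped per CUI."""
    entries: dict[str, LexiconEntry] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, (cui, preferred, variant) in (
        (ln, f) for ln, f in _read_tsv(path, ("cui", "preferred_term", "variant"))
    ):
        if not CUI_PATTERN.match(cui):
            raise ValidationError(f"line {lineno}: invalid CUI code {cui!r}")
        key = (cui, variant.lower())
        if key in seen:
            logger.warning("line %d: duplicate variant %r for %s, dropped", lineno, variant, cui)
            continue
        seen.add(key)
        if cui in entries:
            entries[cui].variants.append(variant)
        else:
            entries[cui] = LexiconEntry(cui=cui, preferred_term=preferred, variants=[variant])
    return Lexicon(entries=entries)


def write_lexicon(lexicon: Lexicon, path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cui\tpreferred_term\tvariant\n")
        for cui in lexicon.entries:
            entry = lexicon.entries[cui]
            for variant in entry.variants:
                fh.write(f"{cui}\t{entry.preferred_term}\t{variant}\n")


def read_curated_terms(path: str | PathLike) -> CuratedLexicon:
    """Read the curated risk/protective term list (TSV: term, category)."""
    terms: list[CuratedTerm] = []
    seen: set[str] = set()
    for lineno, (term, category) in (
        (ln, f) for ln, f in _read_tsv(path, ("term", "category"))
    ):
        if category not in CATEGORIES:
            raise ValidationError(
                f"line {lineno}: unknown category {category!r} for term {term!r}"
            )
        key = term.lower()
        if key in seen:
            logger.warning("line %d: duplicate curated term %r, dropped", lineno, term)
            continue
        seen.add(key)
        terms.append(CuratedTerm(surface_term=term, category=category))
    return CuratedLexicon(terms=terms)


def write_curated_terms(curated: CuratedLexicon, path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tcategory\n")
        for t in curated.terms:
            fh.write(f"{t.surface_term}\t{t.category}\n")
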