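"""Note x CUI dummy matrix construction and feature filtering.

Each note becomes one row of a binary sparse matrix; each distinct feature
code (CUI or CUI_neg) observed anywhere in the corpus becomes one column.
Note labels are inherited from the patient outcome: supervision exists only
at patient level while classification operates note by note (a
multiple-instance structure). To limit overfitting, a code must occur in
notes of at least ``min_patients`` distinct patients to stay in the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .corpus_io import Corpus, CuratedLexicon, Lexicon
from .extraction import ExtractionConfig, NoteCuiSet, extract_corpus, normalize_tokens

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Binary note x feature-code presence matrix with patient keys."""

    note_ids: list[str]
    patient_ids: list[str]
    note_labels: np.ndarray  # shape (n_notes,), values in {0,1}
    codes: list[str]
    matrix: sp.csr_matrix  # dtype int8, values in {0,1}

    def __post_init__(self) -> None:
        n, p = self.matrix.shape
        if not (len(self.note_ids) == len(self.patient_ids) == len(self.note_labels) == n):
            raise ValueError("row index lengths disagree with matrix shape")
        if len(self.codes) != p:
            raise ValueError("column index length disagrees with matrix shape")
        if len(set(self.codes)) != p:
            raise ValueError("duplicate feature codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(mask)
        return FeatureMatrix(
            note_ids=[self.note_ids[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            note_labels=self.note_labels[idx],
            codes=list(self.codes),
            matrix=self.matrix[idx],
        )

    def rows_for_patients(self, patient_ids: set[str]) -> "FeatureMatrix":
        mask = np.array([pid in patient_ids for pid in self.patient_ids])
        return self.subset_rows(mask)

    def subset_codes(self, codes: list[str]) -> "FeatureMatrix":
        pos = {c: j for j, c in enumerate(self.codes)}
        idx = [pos[c] for c in codes]
        return FeatureMatrix(
            note_ids=list(self.note_ids),
            patient_ids=list(self.patient_ids),
            note_labels=self.note_labels.copy(),
            codes=list(codes),
            matrix=self.matrix[:, idx].tocsr(),
        )

    def codes_present(self) -> list[str]:
        """Codes with at least one occurrence in the current rows."""
        col_counts = np.asarray(self.matrix.sum(axis=0)).ravel()
        return [c for c, n in zip(self.codes, col_counts) if n > 0]


def build_note_matrix(cui_sets: list[NoteCuiSet], corpus: Corpus) -> FeatureMatrix:
    """One row per note set, one column per code observed anywhere; columns
    in lexicographic code order, rows in input order."""
    labels = corpus.labels()
    known = corpus.note_index()
    codes = sorted({c for s in cui_sets for c in s.feature_codes})
    col = {c: j for j, c in enumerate(codes)}
    rows, cols = [], []
    note_ids, patient_ids, note_labels = [], [], []
    for i, s in enumerate(cui_sets):
        if s.note_id not in known:
            raise ValueError(f"unknown note_id {s.note_id!r}")
        note_ids.append(s.note_id)
        patient_ids.append(s.patient_id)
        note_labels.append(labels[s.patient_id])
        for c in s.feature_codes:
            rows.append(i)
            cols.append(col[c])
    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(cui_sets), len(codes)),
    )
    return FeatureMatrix(
        note_ids=note_ids,
        patient_ids=patient_ids,
        note_labels=np.array(note_labels, dtype=np.int8),
        codes=codes,
        matrix=matrix,
    )


def distinct_patient_counts(matrix: FeatureMatrix) -> np.ndarray:
    """Per column: number of distinct patients with >=1 note containing it."""
    pids = np.array(matrix.patient_ids)
    _, inv = np.unique(pids, return_inverse=True)
    n_pat = inv.max() + 1 if len(inv) else 0
    # patient x code incidence, then count nonzero patients per code
    coo = matrix.matrix.tocoo()
    pat_code = sp.csr_matrix(
        (np.ones(len(coo.data), dtype=np.int32), (inv[coo.row], coo.col)),
        shape=(n_pat, matrix.shape[1]),
    )
    return np.asarray((pat_code > 0).sum(axis=0)).ravel()


def filter_min_patients(matrix: FeatureMatrix, min_patients: int = 4) -> FeatureMatrix:
    """Keep only codes occurring in notes of >= min_patients distinct
    patients; rows unchanged."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    counts = distinct_patient_counts(matrix)
    keep = [c for c, n in zip(matrix.codes, counts) if n >= min_patients]
    logger.info(
        "min-patient filter (>=%d): %d -> %d codes",
        min_patients, len(matrix.codes), len(keep),
    )
    return matrix.subset_codes(keep)


@dataclass
class CuratedCuiSet:
    """Feature codes a curated term list resolves to in a given corpus."""

    codes: set[str]
    provenance: dict[str, str] = field(default_factory=dict)  # code -> curated term
    unmatched_terms: list[str] = field(default_factory=list)


def _is_token_subsequence(needle: tuple[str, ...], haystack: tuple[str, ...]) -> bool:
    if not needle or len(needle) > len(haystack):
        return False
    return any(
        haystack[i : i + len(needle)] == needle
        for i in range(len(haystack) - len(needle) + 1)
    )


def resolve_curated(
    curated: CuratedLexicon,
    corpus: Corpus,
    lexicon: Lexicon,
    cui_sets: list[NoteCuiSet] | None = None,
    extraction_config: ExtractionConfig | None = None,
) -> CuratedCuiSet:
    """Map curated surface terms to observed feature codes.

    A curated term maps to every CUI one of whose lexicon variants contains
    the term as a contiguous token subsequence (case-insensitive), provided
    that CUI was observed in at least one corpus note (affirmed or negated
    form). Unmatched terms are reported, not errors. Pass precomputed
    ``cui_sets`` to avoid re-extracting the corpus.
    """
    if cui_sets is None:
        cui_sets = extract_corpus(corpus, lexicon, extraction_config)
    observed: set[str] = set()
    for s in cui_sets:
        observed.update(s.feature_codes)
    observed_cuis = {c.removesuffix("_neg") for c in observed}

    codes: set[str] = set()
    provenance: dict[str, str] = {}
    unmatched: list[str] = []
    for t in curated.terms:
        term_tokens = tuple(tok for tok, _, _ in normalize_tokens(t.surface_term))
        hit = False
        for cui in sorted(lexicon.entries):
            if cui not in observed_cuis:
                continue
            for variant in lexicon.entries[cui].variants:
                var_tokens = tuple(tok for tok, _, _ in normalize_tokens(variant))
                if _is_token_subsequence(term_tokens, var_tokens):
                    for code in (cui, cui + "_neg"):
                        if code in observed:
                            codes.add(code)
                            provenance.setdefault(code, t.surface_term)
                            hit = True
                    break
        if not hit:
            unmatched.append(t.surface_term)
    if unmatched:
        logger.info("%d curated terms matched nothing in the corpus", len(unmatched))
    return CuratedCuiSet(codes=codes, provenance=provenance, unmatched_terms=unmatched)


# ---------------------------------------------------------------------------
# MTX serialization (sparse coordinate file + row/column sidecar TSVs)


def write_matrix(matrix: FeatureMatrix, prefix: str | PathLike) -> None:
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), matrix.matrix.tocoo())
    with open(prefix.with_suffix(".rows.tsv"), "w", encoding="utf-8") as fh:
        fh.write("note_id\tpatient_id\tnote_label\n")
        for nid, pid, lab in zip(matrix.note_ids, matrix.patient_ids, matrix.note_labels):
            fh.write(f"{nid}\t{pid}\t{int(lab)}\n")
    with open(prefix.with_suffix(".cols.tsv"), "w", encoding="utf-8") as fh:
        fh.write("code\n")
        for c in matrix.codes:
            fh.write(c + "\n")


def read_matrix(prefix: str | PathLike) -> FeatureMatrix:
    prefix = Path(prefix)
    mat = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx")))).astype(np.int8)
    note_ids, patient_ids, labels = [], [], []
    with open(prefix.with_suffix(".rows.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            nid, pid, lab = line.rstrip("\n").split("\t")
            note_ids.append(nid)
            patient_ids.append(pid)
            labels.append(int(lab))
    with open(prefix.with_suffix(".cols.tsv"), encoding="utf-8") as fh:
        next(fh)
        codes = [line.rstrip("\n") for line in fh if line.strip()]
    return FeatureMatrix(
        note_ids=note_ids,
        patient_ids=patient_ids,
        note_labels=np.array(labels, dtype=np.int8),
        codes=codes,
        matrix=mat,
    )
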