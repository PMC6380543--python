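import numpy as np
import pytest

from suicidality_pipeline.corpus_io import Lexicon, LexiconEntry
from suicidality_pipeline.extraction import NoteCuiSet
from suicidality_pipeline.features import (
    build_note_matrix,
    distinct_patient_counts,
    filter_min_patients,
    read_matrix,
    resolve_curated,
    write_matrix,
)
from suicidality_pipeline.synthetic import build_default_curated_terms

from conftest import make_corpus


def sets_for(corpus, codes_by_note):
    owner = {n.note_id: n.patient_id for n in corpus.notes}
    return [
        NoteCuiSet(nid, owner[nid], set(codes))
        for nid, codes in codes_by_note.items()
    ]


class TestBuildMatrix:
    def test_hand_construction(self):
        corpus = make_corpus([1, 0], texts={"p1": ["a", "b"], "p2": ["c"]})
        cui_sets = sets_for(
            corpus,
            {"p1-n1": {"C0000001"}, "p1-n2": {"C0000001", "C0000002"}, "p2-n1": set()},
        )
        m = build_note_matrix(cui_sets, corpus)
        assert m.shape == (3, 2)
        assert list(np.asarray(m.matrix.sum(axis=1)).ravel()) == [1, 2, 0]
        assert list(m.note_labels) == [1, 1, 0]  # labels inherited from patients

    def test_no_codes_anywhere(self):
        corpus = make_corpus([1, 0])
        m = build_note_matrix(sets_for(corpus, {"p1-n1": set(), "p2-n1": set()}), corpus)
        assert m.shape == (2, 0)

    def test_unknown_note_rejected(self):
        corpus = make_corpus([1, 0])
        bad = [NoteCuiSet("ghost", "p1", {"C0000001"})]
        with pytest.raises(ValueError, match="ghost"):
            build_note_matrix(bad, corpus)

    def test_cells_equal_membership(self):
        rng = np.random.default_rng(5)
        corpus = make_corpus([1, 0, 1, 0], notes_per_patient=5)
        codes = [f"C{1000000 + i}" for i in range(12)]
        by_note = {
            n.note_id: {c for c in codes if rng.random() < 0.3} for n in corpus.notes
        }
        m = build_note_matrix(sets_for(corpus, by_note), corpus)
        dense = m.matrix.toarray()
        for _ in range(1000):
            i = rng.integers(m.shape[0])
            j = rng.integers(m.shape[1])
            assert dense[i, j] == (m.codes[j] in by_note[m.note_ids[i]])

    def test_row_order_follows_input(self):
        corpus = make_corpus([1, 0], texts={"p1": ["a"], "p2": ["b"]})
        by_note = {"p2-n1": {"C0000009"}, "p1-n1": set()}
        m = build_note_matrix(sets_for(corpus, by_note), corpus)
        assert m.note_ids == ["p2-n1", "p1-n1"]


class TestFilterMinPatients:
    def _matrix(self, placements, n_patients=6, notes_per_patient=3):
        """placements: code -> list of (patient index 1-based, note index 1-based)."""
        corpus = make_corpus([i % 2 for i in range(n_patients)], notes_per_patient)
        by_note = {n.note_id: set() for n in corpus.notes}
        for code, spots in placements.items():
            for pi, ni in spots:
                by_note[f"p{pi}-n{ni}"].add(code)
        return build_note_matrix(sets_for(corpus, by_note), corpus)

    def test_three_patients_dropped_four_kept(self):
        m = self._matrix(
            {
                "C0000001": [(1, 1), (2, 1), (3, 1)],
                "C0000002": [(1, 2), (2, 2), (3, 2), (4, 1)],
            }
        )
        out = filter_min_patients(m, 4)
        assert out.codes == ["C0000002"]
        assert out.shape[0] == m.shape[0]

    def test_distinct_patient_counting_not_note_counting(self):
        m = self._matrix({"C0000001": [(1, i) for i in range(1, 11)]},
                         n_patients=4, notes_per_patient=10)
        assert filter_min_patients(m, 4).codes == []

    def test_min_one_is_identity(self):
        m = self._matrix({"C0000001": [(1, 1)], "C0000002": [(2, 1), (3, 1)]})
        assert filter_min_patients(m, 1).codes == m.codes

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(11)
        placements = {
            f"C{1000000 + c}": [
                (int(rng.integers(1, 7)), int(rng.integers(1, 4))) for _ in range(rng.integers(1, 9))
            ]
            for c in range(15)
        }
        m = self._matrix(placements)
        once = filter_min_patients(m, 3)
        assert filter_min_patients(once, 3).codes == once.codes
        stricter = filter_min_patients(m, 4)
        assert set(stricter.codes) <= set(once.codes)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(23)
        corpus = make_corpus([1, 0, 1, 0, 1], notes_per_patient=4)
        codes = [f"C{2000000 + i}" for i in range(10)]
        by_note = {
            n.note_id: {c for c in codes if rng.random() < 0.25} for n in corpus.notes
        }
        m = build_note_matrix(sets_for(corpus, by_note), corpus)
        counts = distinct_patient_counts(m)
        owner = {n.note_id: n.patient_id for n in corpus.notes}
        for j, code in enumerate(m.codes):
            brute = len({owner[nid] for nid, cs in by_note.items() if code in cs})
            assert counts[j] == brute


class TestResolveCurated:
    def lexicon(self):
        return Lexicon(
            entries={
                "C0000001": LexiconEntry("C0000001", "Suicide attempt", ["suicide attempt", "suicide attempts"]),
                "C0000002": LexiconEntry("C0000002", "Attempted suicide", ["attempted suicide attempt"]),
                "C0000003": LexiconEntry("C0000003", "Headache", ["headache"]),
            }
        )

    def test_term_present_in_corpus_resolves(self):
        corpus = make_corpus([1], texts={"p1": ["History of suicide attempt noted."]})
        cur = build_default_curated_terms()
        out = resolve_curated(cur, corpus, self.lexicon())
        assert "C0000001" in out.codes
        assert out.provenance["C0000001"] == "suicide attempt"

    def test_unmatched_terms_reported_not_error(self):
        corpus = make_corpus([1], texts={"p1": ["Nothing clinical here."]})
        cur = build_default_curated_terms()
        out = resolve_curated(cur, corpus, self.lexicon())
        assert out.codes == set()
        assert "suicide attempt" in out.unmatched_terms

    def test_term_matching_two_cuis_includes_both(self):
        corpus = make_corpus(
            [1],
            texts={"p1": ["Noted suicide attempt. Past attempted suicide attempt."]},
        )
        cur = build_default_curated_terms()
        out = resolve_curated(cur, corpus, self.lexicon())
        assert {"C0000001", "C0000002"} <= out.codes

    def test_negated_form_included_when_observed(self):
        corpus = make_corpus([1], texts={"p1": ["No suicide attempts this year."]})
        cur = build_default_curated_terms()
        out = resolve_curated(cur, corpus, self.lexicon())
        assert "C0000001_neg" in out.codes and "C0000001" not in out.codes


class TestMatrixSerialization:
    def test_mtx_round_trip(self, tmp_path):
        corpus = make_corpus([1, 0], texts={"p1": ["a", "b"], "p2": ["c"]})
        cui_sets = sets_for(
            corpus,
            {"p1-n1": {"C0000001"}, "p1-n2": {"C0000001", "C0000002"}, "p2-n1": set()},
        )
        m = build_note_matrix(cui_sets, corpus)
        write_matrix(m, tmp_path / "mat")
        back = read_matrix(tmp_path / "mat")
        assert back.note_ids == m.note_ids
        assert back.codes == m.codes
        assert (back.matrix.toarray() == m.matrix.toarray()).all()
        assert list(back.note_labels) == list(m.note_labels)
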