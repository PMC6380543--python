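import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from suicidality_pipeline.corpus_io import Corpus, Note, Patient
from suicidality_pipeline.synthetic import build_default_curated_terms, build_default_lexicon

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_corpus(labels, notes_per_patient=1, texts=None):
    """Corpus with patients p1..pn and sequentially numbered notes.

    texts: optional dict patient_id -> list of note texts (overrides
    notes_per_patient for that patient).
    """
    patients = {}
    notes = []
    day = dt.date(2015, 6, 1)
    for i, lab in enumerate(labels, start=1):
        pid = f"p{i}"
        patients[pid] = Patient(pid, lab)
        body = (texts or {}).get(pid)
        if body is None:
            body = ["Patient seen in clinic today."] * notes_per_patient
        for k, text in enumerate(body, start=1):
            notes.append(Note(f"{pid}-n{k}", pid, day, text))
    return Corpus(patients=patients, notes=notes)


@pytest.fixture(scope="session")
def default_lexicon():
    return build_default_lexicon()


@pytest.fixture(scope="session")
def default_curated():
    return build_default_curated_terms()


@pytest.fixture()
def tiny_corpus():
    return make_corpus(
        [1, 0],
        texts={
            "p1": ["No suicide attempts. Reports severe depression.",
                   "Endorses thoughts of suicide."],
            "p2": ["Denies feeling suicidal today.", "Patient reports headache."],
        },
    )
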