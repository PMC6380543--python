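"""Synthetic EHR-note cohort generator.

Emulates the statistical structure of a psychiatric-inpatient adolescent
cohort with pre-admission clinical notes: ~37% of patients report a
past-year suicide attempt, notes-per-patient is strongly right-skewed
(log-normal, clipped to [1, 876]; defaults give mean ~129 and median ~70),
and note text is assembled from sentence templates whose concept terms are
sampled at label-conditional per-note rates. Negation triggers ("denies",
"no", "without", ...) wrap a configurable fraction of mentions so the
extractor's negation logic is exercised; negated mentions of signal
concepts are more frequent for unaffected patients, mirroring "no suicide
attempts"-style documentation.

Template text is deliberately schematic — it exercises extraction and the
learning pipeline, it does not imitate clinical prose.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    Corpus,
    CuratedLexicon,
    CuratedTerm,
    Lexicon,
    LexiconEntry,
    Note,
    Patient,
)

INDEX_DATE = dt.date(2016, 1, 1)

# (cui, preferred_term, variants); codes other than C0424000 are opaque
# synthetic identifiers in the UMLS "C#######" format.
_DEFAULT_LEXICON_ROWS: list[tuple[str, str, list[str]]] = [
    # --- suicide-related / acute risk (default signal cluster) ---
    ("C0424000", "Feeling suicidal (finding)", ["feeling suicidal", "suicidal"]),
    ("C1000001", "Suicide attempt", ["suicide attempt", "suicide attempts", "attempted suicide"]),
    ("C1000002", "Suicidal thoughts", ["thoughts of suicide", "suicidal thoughts", "suicidal ideation"]),
    ("C1000003", "Self harm", ["self harm", "self injury", "cutting"]),
    ("C1000004", "Hopelessness", ["hopelessness", "hopeless"]),
    ("C1000005", "Drug overdose", ["overdose", "took pills"]),
    ("C1000006", "Depressed mood", ["depressed mood", "mood depressed", "depressed"]),
    ("C1000007", "Severe depression", ["severe depression"]),
    ("C1000008", "Pain", ["pain"]),
    ("C1000009", "Psychiatric hospitalization", ["psychiatric hospitalization", "inpatient admission"]),
    # --- family relations ---
    ("C1000010", "Father", ["father", "fathers", "dad"]),
    ("C1000011", "Brother", ["brother", "brothers"]),
    ("C1000012", "Grandfather", ["grandfather"]),
    ("C1000013", "Parent", ["parent", "parents"]),
    ("C1000014", "Sibling", ["sibling", "siblings"]),
    ("C1000015", "Mother", ["mother", "mothers", "mom"]),
    ("C1000016", "Sister", ["sister", "sisters"]),
    ("C1000017", "Family conflict", ["family conflict", "conflict at home"]),
    # --- psychiatric disorders / symptoms ---
    ("C1000018", "Posttraumatic stress disorder", ["ptsd", "posttraumatic stress disorder"]),
    ("C1000019", "Unspecified psychosis", ["unspecified psychosis", "psychosis"]),
    ("C1000020", "Bipolar disorder", ["bipolar disorder", "bipolar"]),
    ("C1000021", "Substance abuse", ["substance abuse", "substance use"]),
    ("C1000022", "Attention deficit hyperactivity disorder", ["adhd", "attention deficit hyperactivity disorder"]),
    ("C1000023", "Anxiety", ["anxiety", "anxious"]),
    ("C1000024", "Panic attack", ["panic attack", "panic attacks"]),
    ("C1000025", "Eating disorder", ["eating disorder", "restricting intake"]),
    ("C1000026", "Insomnia", ["insomnia", "trouble sleeping"]),
    ("C1000027", "Anhedonia", ["anhedonia", "loss of interest"]),
    ("C1000028", "Agitation", ["agitation", "agitated"]),
    ("C1000029", "Aggression", ["aggression", "aggressive behavior"]),
    ("C1000030", "Trauma history", ["trauma", "trauma history"]),
    ("C1000031", "Impulsivity", ["impulsivity", "impulsive"]),
    # --- psychotropic / other medications ---
    ("C1000032", "Antidepressant", ["antidepressant", "antidepressants"]),
    ("C1000033", "SSRI", ["ssri", "fluoxetine", "sertraline"]),
    ("C1000034", "Antipsychotic", ["antipsychotic", "risperidone"]),
    ("C1000035", "Mood stabilizer", ["mood stabilizer", "lithium"]),
    ("C1000036", "Anti-inflammatory agent", ["anti inflammatory", "ibuprofen"]),
    ("C1000037", "Stimulant", ["stimulant", "methylphenidate"]),
    ("C1000038", "Benzodiazepine", ["benzodiazepine", "lorazepam"]),
    ("C1000039", "Melatonin", ["melatonin"]),
    # --- protective factors ---
    ("C1000040", "Safety plan", ["safety plan"]),
    ("C1000041", "Family support", ["family support", "supportive family"]),
    ("C1000042", "Therapy engagement", ["therapy engagement", "engaged in therapy"]),
    ("C1000043", "Coping skills", ["coping skills"]),
    ("C1000044", "Future orientation", ["future orientation", "future oriented"]),
    ("C1000045", "School engagement", ["school engagement", "doing well in school"]),
    ("C1000046", "Social support", ["social support"]),
    ("C1000047", "Medication adherence", ["medication adherence", "compliant with medication"]),
    ("C1000048", "Exercise", ["exercise", "physical activity"]),
    ("C1000049", "Close friendships", ["close friends", "good friends"]),
    ("C1000050", "Religious involvement", ["religious involvement", "attends church"]),
    # --- general clinical noise ---
    ("C1000051", "Headache", ["headache", "headaches"]),
    ("C1000052", "Appetite", ["appetite"]),
    ("C1000053", "Fatigue", ["fatigue", "tired"]),
    ("C1000054", "Nausea", ["nausea"]),
    ("C1000055", "Asthma", ["asthma"]),
    ("C1000056", "Seasonal allergies", ["allergies", "allergic rhinitis"]),
    ("C1000057", "Immunization", ["immunization", "vaccination"]),
    ("C1000058", "Sore throat", ["sore throat"]),
    ("C1000059", "Weight", ["weight"]),
    ("C1000060", "Homework", ["homework"]),
    ("C1000061", "Sleep hygiene", ["sleep hygiene"]),
]

#: CUIs whose per-note mention rate depends on the attempt label by default
DEFAULT_SIGNAL_CUIS = (
    "C0424000", "C1000001", "C1000002", "C1000003", "C1000004",
    "C1000005", "C1000006", "C1000007", "C1000008", "C1000009",
)

_RISK_TERMS = [
    "suicide attempt", "thoughts of suicide", "feeling suicidal", "self harm",
    "hopelessness", "overdose", "depressed mood", "severe depression", "pain",
    "family conflict", "ptsd", "psychosis", "bipolar", "substance abuse",
    "attention deficit hyperactivity disorder", "anxiety", "panic attack",
    "eating disorder", "insomnia", "anhedonia", "agitation", "aggression",
    "trauma", "psychiatric hospitalization", "impulsivity", "bullying",
    "isolation", "abuse history", "neglect", "running away", "legal problems",
    "school failure", "grief", "firearm access",
]  # 34
_PROTECTIVE_TERMS = [
    "family support", "safety plan", "therapy engagement", "coping skills",
    "future orientation", "school engagement", "social support",
    "medication adherence", "exercise", "close friends",
    "religious involvement", "supportive parents", "problem solving skills",
    "help seeking", "stable housing", "mentorship", "emotion regulation",
    "optimism", "self esteem", "community involvement", "sports participation",
    "academic achievement", "family cohesion", "treatment alliance",
    "resilience", "spirituality", "volunteering", "structured routine",
    "positive peer relationships", "hobbies",
]  # 30

_AFFIRMED_TEMPLATES = [
    "Patient reports {}.",
    "Discussed {} in session.",
    "History of {} noted.",
    "Endorses {} today.",
    "Ongoing {} per guardian.",
]
_NEGATED_TEMPLATES = [
    "Denies {}.",
    "No {} reported.",
    "Without {} at this time.",
    "Patient denies {} today.",
    "Negative for {}.",
]
_FILLER_SENTENCES = [
    "Patient seen in clinic today.",
    "Met with clinician for supportive session.",
    "Vitals reviewed and stable.",
    "Plan reviewed with guardian.",
    "Will return next week.",
]

_SEXES = ["female", "male"]
_RACES = ["white", "hispanic", "black", "asian", "other"]
_RACE_P = [0.55, 0.20, 0.13, 0.05, 0.07]
_INSURANCE = ["public", "private"]
_INSURANCE_P = [0.67, 0.33]


def build_default_lexicon() -> Lexicon:
    """Shipped default CUI lexicon (62 concepts across the clusters a
    psychiatric note corpus exhibits: suicide-related terms, family
    relations, psychiatric disorders, psychotropic medications, protective
    factors, general clinical noise)."""
    return Lexicon(
        entries={
            cui: LexiconEntry(cui=cui, preferred_term=pref, variants=list(vs))
            for cui, pref, vs in _DEFAULT_LEXICON_ROWS
        }
    )


def build_default_curated_terms() -> CuratedLexicon:
    """Shipped default curated list: 34 risk and 30 protective terms."""
    return CuratedLexicon(
        terms=[CuratedTerm(t, "risk") for t in _RISK_TERMS]
        + [CuratedTerm(t, "protective") for t in _PROTECTIVE_TERMS]
    )


class ConfigError(ValueError):
    """Generator configuration violates its domain."""


@dataclass
class GeneratorConfig:
    """Conditions of a simulated cohort.

    Per-note mention rates are Bernoulli probabilities: for each note and
    each configured CUI, one mention is emitted with the (label-conditional)
    rate. ``negation_rate`` is the probability a mention is rendered inside
    a negation template; for signal CUIs in label-0 patients it is
    multiplied by ``label0_negation_multiplier`` (capped at 0.95).
    """

    n_patients: int = 73
    prevalence: float = 0.37
    #: log-normal parameters of the notes-per-patient count
    notes_mu: float = 4.25
    notes_sigma: float = 1.15
    notes_range: tuple[int, int] = (1, 876)
    lexicon: Lexicon | None = None
    #: (cui, rate_if_positive, rate_if_negative)
    signal_cuis: list[tuple[str, float, float]] | None = None
    #: (cui, base_rate), label-independent
    noise_cuis: list[tuple[str, float]] | None = None
    negation_rate: float = 0.15
    label0_negation_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lexicon is None:
            self.lexicon = build_default_lexicon()
        if self.signal_cuis is None:
            self.signal_cuis = [(c, 0.15, 0.05) for c in DEFAULT_SIGNAL_CUIS]
        if self.noise_cuis is None:
            signal = {c for c, _, _ in self.signal_cuis}
            self.noise_cuis = [
                (c, 0.04) for c in self.lexicon.entries if c not in signal
            ]
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("prevalence must lie in [0, 1]")
        if self.notes_sigma < 0:
            raise ConfigError("notes_sigma must be >= 0")
        lo, hi = self.notes_range
        if not 1 <= lo <= hi:
            raise ConfigError("notes_range must satisfy 1 <= lo <= hi")
        if self.notes_sigma == 0 and not lo <= round(np.exp(self.notes_mu)) <= hi:
            raise ConfigError(
                "zero-variance notes distribution falls outside notes_range"
            )
        for cui, *rates in list(self.signal_cuis) + list(self.noise_cuis):
            if cui not in self.lexicon:
                raise ConfigError(f"configured CUI {cui} missing from lexicon")
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ConfigError(f"rate out of [0, 1] for CUI {cui}")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ConfigError("negation_rate must lie in [0, 1]")
        if self.label0_negation_multiplier < 0:
            raise ConfigError("label0_negation_multiplier must be >= 0")


def strong_signal_config(n_patients: int = 400, seed: int = 0, **overrides) -> GeneratorConfig:
    """Cohort with strongly label-separated mention rates (10 signal CUIs at
    0.30 vs 0.02 per note)."""
    cfg = dict(
        n_patients=n_patients,
        seed=seed,
        signal_cuis=[(c, 0.30, 0.02) for c in DEFAULT_SIGNAL_CUIS],
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def null_config(n_patients: int = 400, seed: int = 0, **overrides) -> GeneratorConfig:
    """Cohort with no label signal: equal mention rates for both labels and
    label-independent negation."""
    cfg = dict(
        n_patients=n_patients,
        seed=seed,
        signal_cuis=[(c, 0.10, 0.10) for c in DEFAULT_SIGNAL_CUIS],
        label0_negation_multiplier=1.0,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def _note_text(rng: np.random.Generator, label: int, config: GeneratorConfig) -> str:
    lex = config.lexicon
    sentences = [
        _FILLER_SENTENCES[rng.integers(len(_FILLER_SENTENCES))]
    ]
    mention_plan: list[tuple[str, float]] = []  # (cui, negation prob)
    for cui, rate_pos, rate_neg in config.signal_cuis:
        rate = rate_pos if label == 1 else rate_neg
        if rng.random() < rate:
            p_neg = config.negation_rate
            if label == 0:
                p_neg = min(0.95, p_neg * config.label0_negation_multiplier)
            mention_plan.append((cui, p_neg))
    for cui, rate in config.noise_cuis:
        if rng.random() < rate:
            mention_plan.append((cui, config.negation_rate))
    for cui, p_neg in mention_plan:
        variants = lex.entries[cui].variants
        term = variants[rng.integers(len(variants))]
        if rng.random() < p_neg:
            tpl = _NEGATED_TEMPLATES[rng.integers(len(_NEGATED_TEMPLATES))]
        else:
            tpl = _AFFIRMED_TEMPLATES[rng.integers(len(_AFFIRMED_TEMPLATES))]
        sentences.append(tpl.format(term))
    return " ".join(sentences)


def generate_cohort(config: GeneratorConfig) -> Corpus:
    """Draw a full synthetic cohort; identical config (incl. seed) yields a
    byte-identical corpus."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.notes_range
    width = len(str(config.n_patients))
    patients: dict[str, Patient] = {}
    notes: list[Note] = []
    for i in range(config.n_patients):
        pid = f"p{i + 1:0{width}d}"
        label = int(rng.random() < config.prevalence)
        demographics = {
            "age": str(int(rng.integers(12, 21))),
            "sex": _SEXES[int(rng.random() < 0.43)],
            "race_ethnicity": _RACES[rng.choice(len(_RACES), p=_RACE_P)],
            "insurance": _INSURANCE[rng.choice(len(_INSURANCE), p=_INSURANCE_P)],
        }
        patients[pid] = Patient(pid, label, demographics)
        if config.notes_sigma == 0:
            n_notes = int(np.clip(round(np.exp(config.notes_mu)), lo, hi))
        else:
            n_notes = int(
                np.clip(round(rng.lognormal(config.notes_mu, config.notes_sigma)), lo, hi)
            )
        days = np.sort(rng.integers(1, 366, size=n_notes))[::-1]  # oldest last year first
        for k in range(n_notes):
            ts = INDEX_DATE - dt.timedelta(days=int(days[k]))
            notes.append(
                Note(
                    note_id=f"{pid}-n{k + 1:03d}",
                    patient_id=pid,
                    timestamp=ts,
                    text=_note_text(rng, label, config),
                )
            )
    return Corpus(patients=patients, notes=notes)


def summarize_cohort(corpus: Corpus) -> dict[str, float]:
    """Descriptive statistics of a cohort: size, label prevalence, and the
    notes-per-patient distribution (mean, median, min, max)."""
    if corpus.n_patients == 0:
        raise ValueError("cannot summarize an empty corpus")
    counts = np.array([len(v) for v in corpus.notes_by_patient().values()])
    labels = np.array([p.attempt_label for p in corpus.patients.values()])
    return {
        "n_patients": int(corpus.n_patients),
        "n_notes": int(corpus.n_notes),
        "prevalence": float(labels.mean()),
        "notes_per_patient_mean": float(counts.mean()),
        "notes_per_patient_median": float(np.median(counts)),
        "notes_per_patient_min": int(counts.min()),
        "notes_per_patient_max": int(counts.max()),
    }
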