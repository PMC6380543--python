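"""Model/Results facade over the full classification pipeline.

``NoteBasedAttemptClassifier`` is built from a corpus plus lexicons (in
memory or from files); ``fit()`` runs extraction, matrix construction,
the min-patient filter, the patient-level 80/20 split, 5-fold
cross-validated feature selection and cutoff choice, and the one-shot
holdout evaluation, returning an ``AttemptClassificationResults`` carrying
the per-cutoff tables, the selected operating point, the holdout metrics
and ROC, and a ``summary()`` in the style of a statistical results table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from os import PathLike
from pathlib import Path

import pandas as pd

from . import corpus_io, evaluation, extraction, features, pipeline
from .corpus_io import Corpus, CuratedLexicon, Lexicon
from .synthetic import build_default_curated_terms, build_default_lexicon


@dataclass
class PipelineSettings:
    """Fixed constants of the procedure, overridable for experimentation."""

    train_fraction: float = pipeline.DEFAULT_TRAIN_FRACTION
    k_folds: int = pipeline.DEFAULT_K_FOLDS
    top_k: int = pipeline.DEFAULT_TOP_K
    min_patients: int = 4
    n_trees: int = pipeline.DEFAULT_N_TREES
    sens_floor: float = pipeline.DEFAULT_SENS_FLOOR
    cutoff_override: float | None = None
    stratified_split: bool = False
    stem: bool = False
    final_feature_mode: str = "reselect"  # or "union"
    negation_window: int = extraction.DEFAULT_WINDOW

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_patients < 1:
            raise ValueError("min_patients must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 <= self.sens_floor <= 1.0:
            raise ValueError("sens_floor must lie in [0, 1]")
        if self.cutoff_override is not None and self.cutoff_override not in pipeline.CUTOFF_GRID:
            raise ValueError("cutoff_override must be a grid value 0.0, 0.1, ..., 1.0")
        if self.final_feature_mode not in ("reselect", "union"):
            raise ValueError("final_feature_mode must be 'reselect' or 'union'")


class NoteBasedAttemptClassifier:
    """Classify past-year suicide attempt from pre-admission note text."""

    def __init__(
        self,
        corpus: Corpus,
        lexicon: Lexicon | None = None,
        curated: CuratedLexicon | None = None,
        settings: PipelineSettings | None = None,
    ) -> None:
        self.corpus = corpus
        self.lexicon = lexicon or build_default_lexicon()
        self.curated = curated or build_default_curated_terms()
        self.settings = settings or PipelineSettings()
        self.settings.validate()

    @classmethod
    def from_files(
        cls,
        corpus_path: str | PathLike,
        lexicon_path: str | PathLike | None = None,
        curated_path: str | PathLike | None = None,
        settings: PipelineSettings | None = None,
    ) -> "NoteBasedAttemptClassifier":
        return cls(
            corpus=corpus_io.read_corpus(corpus_path),
            lexicon=corpus_io.read_lexicon(lexicon_path) if lexicon_path else None,
            curated=corpus_io.read_curated_terms(curated_path) if curated_path else None,
            settings=settings,
        )

    def fit(self, seed: int = 0) -> "AttemptClassificationResults":
        s = self.settings
        ext_cfg = extraction.ExtractionConfig(stem=s.stem, window=s.negation_window)
        cui_sets = extraction.extract_corpus(self.corpus, self.lexicon, ext_cfg)
        full_matrix = features.build_note_matrix(cui_sets, self.corpus)
        filtered = features.filter_min_patients(full_matrix, s.min_patients)
        curated_set = features.resolve_curated(
            self.curated, self.corpus, self.lexicon, cui_sets=cui_sets
        )
        split_seed, fold_seed, cv_seed, final_seed = pipeline.derive_seeds(seed, 4)
        split = pipeline.split_train_holdout(
            self.corpus, fraction=s.train_fraction, seed=split_seed,
            stratified=s.stratified_split,
        )
        folds = pipeline.assign_folds(split, k=s.k_folds, seed=fold_seed)
        train_matrix = filtered.rows_for_patients(set(split.training_patients))
        cv = pipeline.cross_validate(
            train_matrix, self.corpus, curated_set, folds,
            seed=cv_seed, top_k=s.top_k, n_trees=s.n_trees,
        )
        selected = pipeline.select_cutoff(
            cv.summary, sens_floor=s.sens_floor, override=s.cutoff_override
        )
        holdout = pipeline.finalize_and_evaluate(
            filtered, self.corpus, split, curated_set, selected,
            seed=final_seed, top_k=s.top_k, n_trees=s.n_trees,
            feature_mode=s.final_feature_mode,
            fold_features=cv.fold_features,
        )
        return AttemptClassificationResults(
            model=self,
            seed=seed,
            n_codes_observed=full_matrix.shape[1],
            n_codes_filtered=filtered.shape[1],
            split=split,
            folds=folds,
            curated_set=curated_set,
            cv=cv,
            selected_cutoff=selected,
            holdout=holdout,
        )


@dataclass
class AttemptClassificationResults:
    """Fitted-pipeline results: tables, operating point, holdout metrics."""

    model: NoteBasedAttemptClassifier
    seed: int
    n_codes_observed: int
    n_codes_filtered: int
    split: pipeline.SplitAssignment
    folds: pipeline.FoldAssignment
    curated_set: features.CuratedCuiSet
    cv: pipeline.CrossValidationResult
    selected_cutoff: float
    holdout: pipeline.HoldoutEvaluation

    @property
    def cv_table(self) -> pd.DataFrame:
        return self.cv.summary

    @property
    def holdout_table(self) -> pd.DataFrame:
        return self.holdout.table

    @property
    def auc(self) -> float | None:
        return self.holdout.roc.auc if self.holdout.roc else None

    def summary(self) -> str:
        h = self.holdout.headline
        cm = self.holdout.headline_confusion
        corpus = self.model.corpus
        lines = [
            "Note-based suicide-attempt classification results",
            "=" * 58,
            f"Patients: {corpus.n_patients}   Notes: {corpus.n_notes}",
            f"Feature codes observed: {self.n_codes_observed}"
            f"   after >= {self.model.settings.min_patients}-patient filter: {self.n_codes_filtered}",
            f"Training patients: {len(self.split.training_patients)}"
            f"   Holdout patients: {len(self.split.holdout_patients)}",
            f"Folds: {self.model.settings.k_folds}"
            f"   Trees: {self.model.settings.n_trees}"
            f"   Top-k Gini features: {self.model.settings.top_k}",
            f"Selected cutoff (CV): {self.selected_cutoff:.0%} of notes",
            "-" * 58,
            "Holdout performance at selected cutoff:",
            f"  confusion: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}",
            f"  sensitivity={h.sensitivity:.2f}  specificity={h.specificity:.2f}",
            f"  PPV={h.ppv:.2f}  NPV={h.npv:.2f}  accuracy={h.accuracy:.2f}",
        ]
        if self.holdout.roc is not None:
            lines.append(f"  AUC over cutoff grid: {self.holdout.roc.auc:.2f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_roc(self, path: str | PathLike | None = None, ax=None):
        """Plot the holdout ROC over the cutoff grid."""
        if self.holdout.roc is None:
            raise ValueError("ROC was not computable for this holdout")
        import matplotlib
        if path is not None and ax is None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(4.5, 4.5))
        xs, ys = zip(*sorted(self.holdout.roc.points))
        ax.plot(xs, ys, marker="o", lw=1.5)
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.set_title(f"AUC = {self.holdout.roc.auc:.2f}")
        if path is not None:
            ax.figure.savefig(path, dpi=120)
        return ax

    def save(self, rundir: str | PathLike) -> None:
        """Write all run artifacts (assignments, per-fold feature report,
        performance tables, ROC, fingerprints, settings snapshot)."""
        rundir = Path(rundir)
        rundir.mkdir(parents=True, exist_ok=True)
        snapshot = {"seed": self.seed, "settings": asdict(self.model.settings)}
        (rundir / "settings.json").write_text(json.dumps(snapshot, indent=2) + "\n")
        with open(rundir / "split.tsv", "w", encoding="utf-8") as fh:
            fh.write("patient_id\tpartition\tfold\n")
            for pid in sorted(self.model.corpus.patients):
                if pid in self.split.training_patients:
                    fh.write(f"{pid}\ttraining\t{self.folds.fold_of[pid]}\n")
                else:
                    fh.write(f"{pid}\tholdout\t\n")
        fold_frames = []
        for f, sel in self.cv.fold_features.items():
            top = sel.ranking.head(self.model.settings.top_k).copy()
            top.insert(0, "fold", f)
            fold_frames.append(top)
        pd.concat(fold_frames).to_csv(
            rundir / "fold_top_features.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        if self.curated_set.unmatched_terms:
            (rundir / "unmatched_curated_terms.txt").write_text(
                "\n".join(self.curated_set.unmatched_terms) + "\n"
            )
        roc = self.holdout.roc
        if roc is None:
            roc = evaluation.RocCurve(points=[(0.0, 0.0), (1.0, 1.0)], auc=0.5)
        evaluation.report_tables(self.cv_table, self.holdout_table, roc, rundir)
        fingerprints = {
            "final_model": self.holdout.model.training_fingerprint,
            **{
                f"fold_{f}": fp for f, fp in self.cv.fold_fingerprints.items()
            },
        }
        (rundir / "fingerprints.json").write_text(json.dumps(fingerprints, indent=2) + "\n")
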