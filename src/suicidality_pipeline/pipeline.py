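"""The note-level random-forest classification pipeline.

Six steps, run strictly on the training side of a patient-level 80/20
split: (1) partition training patients into 5 folds; (2) build the binary
note x CUI matrix (done upstream) and keep codes seen for >=4 distinct
patients; (3) per fold, rank the fold-training codes by random-forest mean
decrease in Gini impurity, keep the top 50 and union in curated codes
present in that fold's training notes; (4) fit a 300-tree random forest on
the fold-training notes over those codes; (5) classify each test-fold note
and aggregate to patients: a patient is called positive at cutoff c when
the fraction of their notes classified positive strictly exceeds c, swept
over the grid 0%, 10%, ..., 100%; (6) average fold metrics per cutoff and
select the operating cutoff (highest mean specificity among cutoffs whose
mean sensitivity clears a floor, default 0.70). A final forest is then
fitted on the full training set and evaluated once on the untouched 20%
holdout.

Note labels are inherited from the patient outcome (multiple-instance
supervision); the holdout never influences feature selection, fitting, or
cutoff choice.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .corpus_io import Corpus
from .evaluation import (
    ConfusionMatrix,
    MetricsRow,
    RocCurve,
    confusion,
    metrics,
    performance_table,
    roc_auc,
    summarize_folds,
)
from .features import CuratedCuiSet, FeatureMatrix

logger = logging.getLogger(__name__)

#: the 11 patient-level proportion cutoffs: 0%, 10%, ..., 100%
CUTOFF_GRID: tuple[float, ...] = tuple(round(c / 10, 1) for c in range(11))

DEFAULT_N_TREES = 300
DEFAULT_TOP_K = 50
DEFAULT_K_FOLDS = 5
DEFAULT_TRAIN_FRACTION = 0.8
DEFAULT_SENS_FLOOR = 0.70


def derive_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) from one master seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass(frozen=True)
class SplitAssignment:
    training_patients: frozenset[str]
    holdout_patients: frozenset[str]
    seed: int


@dataclass(frozen=True)
class FoldAssignment:
    fold_of: dict[str, int]  # patient_id -> fold in 1..k

    @property
    def k(self) -> int:
        return max(self.fold_of.values())

    def patients_in(self, fold: int) -> set[str]:
        return {pid for pid, f in self.fold_of.items() if f == fold}


@dataclass
class TrainedModel:
    feature_codes: list[str]
    forest: RandomForestClassifier
    seed: int
    training_fingerprint: str


@dataclass
class FeatureSelection:
    """Ordered selected codes plus the full importance ranking (the
    per-fold top-50 report)."""

    features: list[str]
    ranking: pd.DataFrame  # columns: code, gini_importance, rank, selected, curated


@dataclass
class PatientPrediction:
    patient_id: str
    n_notes: int
    n_positive_notes: int

    @property
    def proportion_positive(self) -> float:
        return self.n_positive_notes / self.n_notes

    def classified(self, cutoff: float) -> int:
        # strict inequality: at 100% nobody is positive, at 0% anyone with
        # >=1 positive note is
        return int(self.proportion_positive > cutoff + 1e-12)


@dataclass
class CrossValidationResult:
    fold_tables: list[pd.DataFrame]
    summary: pd.DataFrame
    fold_features: dict[int, FeatureSelection]
    fold_fingerprints: dict[int, str]


@dataclass
class HoldoutEvaluation:
    table: pd.DataFrame
    selected_cutoff: float
    headline: MetricsRow
    headline_confusion: ConfusionMatrix
    roc: RocCurve | None
    model: TrainedModel
    feature_selection: FeatureSelection
    patient_predictions: list[PatientPrediction] = field(default_factory=list)


# ---------------------------------------------------------------------------
# partitioning


def split_train_holdout(
    corpus: Corpus,
    fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    stratified: bool = False,
) -> SplitAssignment:
    """Patient-level random split; all a patient's notes travel together."""
    pids = sorted(corpus.patients)
    if len(pids) < 5:
        raise ValueError("need at least 5 patients to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratified:
        train: list[str] = []
        labels = corpus.labels()
        for lab in (0, 1):
            group = [p for p in pids if labels[p] == lab]
            perm = rng.permutation(len(group))
            n_train = int(round(fraction * len(group)))
            train.extend(group[i] for i in perm[:n_train])
        training = frozenset(train)
    else:
        perm = rng.permutation(len(pids))
        n_train = int(round(fraction * len(pids)))
        training = frozenset(pids[i] for i in perm[:n_train])
    holdout = frozenset(p for p in pids if p not in training)
    return SplitAssignment(training_patients=training, holdout_patients=holdout, seed=seed)


def assign_folds(split: SplitAssignment, k: int = DEFAULT_K_FOLDS, seed: int = 0) -> FoldAssignment:
    """Partition training patients into k folds with sizes differing by <=1."""
    pids = sorted(split.training_patients)
    n = len(pids)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, k)
    fold_of: dict[str, int] = {}
    pos = 0
    for f in range(1, k + 1):
        size = base + (1 if f <= rem else 0)
        for i in perm[pos : pos + size]:
            fold_of[pids[i]] = f
        pos += size
    return FoldAssignment(fold_of=fold_of)


# ---------------------------------------------------------------------------
# feature selection and fitting


def _labels_of(matrix: FeatureMatrix) -> np.ndarray:
    return np.asarray(matrix.note_labels, dtype=np.int8)


def select_features_fold(
    train_matrix: FeatureMatrix,
    curated: CuratedCuiSet,
    top_k: int = DEFAULT_TOP_K,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> FeatureSelection:
    """Rank codes by mean decrease in Gini impurity of a ranking forest,
    keep the top_k, and union curated codes present in the training rows.

    ``train_matrix`` must already be restricted to the fold's training notes
    and to codes present in those notes. Importance ties break
    lexicographically by code so the selection is reproducible.
    """
    y = _labels_of(train_matrix)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both note labels present")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(train_matrix.matrix.toarray(), y)
    importances = forest.feature_importances_
    order = sorted(
        range(len(train_matrix.codes)),
        key=lambda j: (-importances[j], train_matrix.codes[j]),
    )
    if top_k > len(order):
        logger.warning(
            "top_k=%d exceeds %d available codes; keeping all",
            top_k, len(order),
        )
    top = [train_matrix.codes[j] for j in order[:top_k]]
    present = set(train_matrix.codes)
    curated_present = sorted((curated.codes & present) - set(top))
    selected = top + curated_present
    rank_of = {train_matrix.codes[j]: r + 1 for r, j in enumerate(order)}
    ranking = pd.DataFrame(
        {
            "code": [train_matrix.codes[j] for j in order],
            "gini_importance": [importances[j] for j in order],
            "rank": [rank_of[train_matrix.codes[j]] for j in order],
            "selected": [train_matrix.codes[j] in set(selected) for j in order],
            "curated": [train_matrix.codes[j] in curated.codes for j in order],
        }
    )
    return FeatureSelection(features=selected, ranking=ranking)


def _fingerprint(matrix: FeatureMatrix, seed: int, n_trees: int) -> str:
    h = hashlib.sha256()
    h.update("\x1f".join(matrix.codes).encode())
    h.update("\x1f".join(matrix.note_ids).encode())
    h.update(np.asarray(matrix.note_labels, dtype=np.int8).tobytes())
    csr = matrix.matrix.tocsr()
    csr.sum_duplicates()
    h.update(np.asarray(csr.indptr, dtype=np.int64).tobytes())
    h.update(np.asarray(csr.indices, dtype=np.int64).tobytes())
    h.update(np.asarray(csr.data, dtype=np.int8).tobytes())
    h.update(f"seed={seed};trees={n_trees}".encode())
    return h.hexdigest()


def train_forest(
    matrix: FeatureMatrix,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    context: str = "training set",
) -> TrainedModel:
    """Fit the 300-tree note-level forest on the given (already
    feature-restricted) matrix."""
    y = _labels_of(matrix)
    if matrix.shape[0] < 2:
        raise ValueError(f"{context}: need at least 2 notes to fit")
    if len(np.unique(y)) < 2:
        raise ValueError(f"degenerate {context}: only one note label present")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(matrix.matrix.toarray(), y)
    return TrainedModel(
        feature_codes=list(matrix.codes),
        forest=forest,
        seed=seed,
        training_fingerprint=_fingerprint(matrix, seed, n_trees),
    )


def predict_notes(model: TrainedModel, matrix: FeatureMatrix) -> dict[str, int]:
    """Binary forest call per note. Columns are aligned to the model's
    feature codes: codes absent from the matrix are imputed as 0, codes the
    model never saw are dropped."""
    if matrix.shape[0] == 0:
        return {}
    pos = {c: j for j, c in enumerate(matrix.codes)}
    X = np.zeros((matrix.shape[0], len(model.feature_codes)), dtype=np.int8)
    dense = None
    for out_j, code in enumerate(model.feature_codes):
        j = pos.get(code)
        if j is not None:
            if dense is None:
                dense = matrix.matrix.toarray()
            X[:, out_j] = dense[:, j]
    preds = model.forest.predict(X)
    return {nid: int(p) for nid, p in zip(matrix.note_ids, preds)}


# ---------------------------------------------------------------------------
# patient-level aggregation


def aggregate_patient(
    note_preds: dict[str, int],
    corpus: Corpus,
    grid: tuple[float, ...] = CUTOFF_GRID,
) -> list[PatientPrediction]:
    """Fraction of positive notes per patient; classification at each grid
    cutoff uses a strict '>' comparison."""
    note_owner = {n.note_id: n.patient_id for n in corpus.notes}
    per_patient: dict[str, list[int]] = {}
    for nid, pred in note_preds.items():
        if nid not in note_owner:
            raise ValueError(f"prediction for unknown note {nid!r}")
        per_patient.setdefault(note_owner[nid], []).append(pred)
    out = []
    for pid in sorted(per_patient):
        preds = per_patient[pid]
        out.append(
            PatientPrediction(
                patient_id=pid,
                n_notes=len(preds),
                n_positive_notes=int(sum(preds)),
            )
        )
    return out


def _score_grid(
    patient_preds: list[PatientPrediction],
    labels: dict[str, int],
    grid: tuple[float, ...],
) -> list[tuple[float, ConfusionMatrix]]:
    lab = {p.patient_id: labels[p.patient_id] for p in patient_preds}
    rows = []
    for c in grid:
        calls = {p.patient_id: p.classified(c) for p in patient_preds}
        rows.append((c, confusion(calls, lab)))
    return rows


# ---------------------------------------------------------------------------
# cross-validation, cutoff selection, holdout


def cross_validate(
    matrix: FeatureMatrix,
    corpus: Corpus,
    curated: CuratedCuiSet,
    folds: FoldAssignment,
    grid: tuple[float, ...] = CUTOFF_GRID,
    seed: int = 0,
    top_k: int = DEFAULT_TOP_K,
    n_trees: int = DEFAULT_N_TREES,
) -> CrossValidationResult:
    """Per fold: select features on the other folds' notes, fit, classify
    the test fold's notes, aggregate patients, score all grid cutoffs; then
    average metrics across folds."""
    labels = corpus.labels()
    k = folds.k
    fold_seeds = derive_seeds(seed, 2 * k)
    fold_tables: list[pd.DataFrame] = []
    fold_features: dict[int, FeatureSelection] = {}
    fold_fingerprints: dict[int, str] = {}
    for f in range(1, k + 1):
        test_pids = folds.patients_in(f)
        train_pids = set(folds.fold_of) - test_pids
        train_m = matrix.rows_for_patients(train_pids)
        # restrict to codes originating from this fold's training notes
        train_m = train_m.subset_codes(train_m.codes_present())
        try:
            sel = select_features_fold(
                train_m, curated, top_k=top_k, seed=fold_seeds[2 * (f - 1)], n_trees=n_trees
            )
            model = train_forest(
                train_m.subset_codes(sel.features),
                seed=fold_seeds[2 * (f - 1) + 1],
                n_trees=n_trees,
                context=f"fold {f}",
            )
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from exc
        test_m = matrix.rows_for_patients(test_pids)
        note_preds = predict_notes(model, test_m)
        patient_preds = aggregate_patient(note_preds, corpus, grid)
        missing = test_pids - {p.patient_id for p in patient_preds}
        if missing:
            logger.warning("fold %d: patients with no notes excluded: %s", f, sorted(missing))
        fold_tables.append(performance_table(_score_grid(patient_preds, labels, grid)))
        fold_features[f] = sel
        fold_fingerprints[f] = model.training_fingerprint
    return CrossValidationResult(
        fold_tables=fold_tables,
        summary=summarize_folds(fold_tables),
        fold_features=fold_features,
        fold_fingerprints=fold_fingerprints,
    )


def select_cutoff(
    cv_table: pd.DataFrame,
    sens_floor: float = DEFAULT_SENS_FLOOR,
    override: float | None = None,
) -> float:
    """Pick the operating cutoff from the CV mean-metric table.

    Default policy (sensitivity-first): among cutoffs whose mean
    sensitivity is >= sens_floor, take the one with the highest mean
    specificity; specificity ties break toward the higher mean sensitivity
    and then the smaller cutoff, so equal specificity never costs recall.
    If no cutoff clears the floor, maximize Youden's J = sensitivity +
    specificity - 1 (same tie-breaks). A manual override bypasses the table.
    """
    if override is not None:
        return float(override)
    if cv_table.empty:
        raise ValueError("empty CV table")
    df = cv_table.sort_values("cutoff").reset_index(drop=True)
    eligible = df[df["sensitivity_mean"] >= sens_floor - 1e-9]
    if len(eligible):
        ranked = eligible.sort_values(
            ["specificity_mean", "sensitivity_mean", "cutoff"],
            ascending=[False, False, True],
        )
    else:
        df = df.assign(youden=df["sensitivity_mean"] + df["specificity_mean"] - 1.0)
        ranked = df.sort_values(
            ["youden", "sensitivity_mean", "cutoff"], ascending=[False, False, True]
        )
    return float(ranked.iloc[0]["cutoff"])


def finalize_and_evaluate(
    matrix: FeatureMatrix,
    corpus: Corpus,
    split: SplitAssignment,
    curated: CuratedCuiSet,
    selected_cutoff: float,
    grid: tuple[float, ...] = CUTOFF_GRID,
    seed: int = 0,
    top_k: int = DEFAULT_TOP_K,
    n_trees: int = DEFAULT_N_TREES,
    feature_mode: str = "reselect",
    fold_features: dict[int, FeatureSelection] | None = None,
) -> HoldoutEvaluation:
    """Fit the final forest on the full training set and score the holdout.

    feature_mode "reselect" re-runs the fold selection procedure on the full
    training matrix; "union" pools the per-fold feature lists instead.
    """
    labels = corpus.labels()
    sel_seed, fit_seed = derive_seeds(seed, 2)
    train_m = matrix.rows_for_patients(set(split.training_patients))
    train_m = train_m.subset_codes(train_m.codes_present())
    if feature_mode == "reselect":
        sel = select_features_fold(train_m, curated, top_k=top_k, seed=sel_seed, n_trees=n_trees)
    elif feature_mode == "union":
        if not fold_features:
            raise ValueError("feature_mode='union' requires fold_features")
        pooled = sorted(
            {c for fs in fold_features.values() for c in fs.features}
            & set(train_m.codes)
        )
        sel = FeatureSelection(
            features=pooled,
            ranking=pd.DataFrame({"code": pooled}),
        )
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    model = train_forest(
        train_m.subset_codes(sel.features), seed=fit_seed, n_trees=n_trees,
        context="final training set",
    )
    holdout_m = matrix.rows_for_patients(set(split.holdout_patients))
    note_preds = predict_notes(model, holdout_m)
    patient_preds = aggregate_patient(note_preds, corpus, grid)
    missing = set(split.holdout_patients) - {p.patient_id for p in patient_preds}
    if missing:
        logger.warning("holdout patients with no notes excluded: %s", sorted(missing))
    scored = _score_grid(patient_preds, labels, grid)
    table = performance_table(scored)
    cutoff_cm = dict(scored)[min(grid, key=lambda c: abs(c - selected_cutoff))]
    try:
        roc = roc_auc([(cm, c) for c, cm in scored])
    except ValueError as exc:
        logger.warning("ROC not computable on holdout: %s", exc)
        roc = None
    return HoldoutEvaluation(
        table=table,
        selected_cutoff=selected_cutoff,
        headline=metrics(cutoff_cm),
        headline_confusion=cutoff_cm,
        roc=roc,
        model=model,
        feature_selection=sel,
        patient_predictions=patient_preds,
    )
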