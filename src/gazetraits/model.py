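"""Per-trait range classification with random forests under nested CV.

A window-level classifier (standard scaler + 100-tree forest, depth 5, up to
15 features per split) is trained on windows labelled with their
participant's trait range; participant predictions are obtained by majority
voting over that participant's windows.  Nested cross-validation rotates
contiguous participant blocks into test (5) and validation (5) sets, picks
the best (window size, feature subset) candidate on the validation set, and
reports only predictions for held-out test participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES, N_FEATURES, feature_subsets, feature_table
from .labels import RANGE_CODE, RANGE_ORDER, TraitBins
from .windows import slide_windows

#: Candidate sliding-window sizes (s) for model selection.
DEFAULT_WINDOW_SIZES = (5.0, 10.0, 15.0, 30.0, 45.0, 60.0)


@dataclass
class ForestSpec:
    n_trees: int = 100
    max_depth: int = 5
    max_features_per_split: int = 15
    seed: int = 0


@dataclass(frozen=True)
class Candidate:
    window_size: float
    subset: str  # key into features.feature_subsets()


def default_candidates(
    window_sizes: Sequence[float] = DEFAULT_WINDOW_SIZES,
    subsets: Sequence[str] | None = None,
) -> list[Candidate]:
    subs = list(subsets) if subsets is not None else list(feature_subsets())
    return [Candidate(w, s) for w in window_sizes for s in subs]


@dataclass
class CohortFeatures:
    """Per-window feature tables for every candidate window size.

    ``tables[size]`` has metadata columns (participant_id, start, end,
    context) followed by the 207 feature columns; ``durations`` maps
    participant to recording length (needed for split-half analyses).
    """

    tables: dict[float, pd.DataFrame]
    durations: dict[str, float]

    @property
    def participants(self) -> list[str]:
        any_table = next(iter(self.tables.values()))
        return sorted(any_table["participant_id"].unique())


def build_cohort_features(
    recordings: Sequence,
    window_sizes: Sequence[float] = DEFAULT_WINDOW_SIZES,
) -> CohortFeatures:
    """Detect events once per recording and extract features per window size."""
    from .events import detect_blinks, detect_fixations, detect_saccades

    tables: dict[float, list[pd.DataFrame]] = {w: [] for w in window_sizes}
    durations: dict[str, float] = {}
    for rec in recordings:
        fixations = detect_fixations(rec)
        saccades = detect_saccades(rec, fixations)
        blinks = detect_blinks(rec)
        durations[rec.participant_id] = rec.duration
        for size in window_sizes:
            ws = slide_windows(rec, fixations, saccades, blinks, size)
            tables[size].append(feature_table(rec, ws))
    return CohortFeatures(
        tables={
            w: pd.concat(parts, ignore_index=True) for w, parts in tables.items()
        },
        durations=durations,
    )


def fit_trait_classifier(
    X: np.ndarray, y: Sequence[str], spec: ForestSpec
) -> Pipeline:
    """Standard scaler + random forest on window features.

    The scaler is fitted on the training rows only (zero-variance features
    are centred but not scaled); the forest uses the printed hyperparameters.
    """
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    clf = Pipeline([
        ("scaler", StandardScaler()),
        ("forest", RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            max_features=spec.max_features_per_split,
            random_state=spec.seed,
            n_jobs=1,
        )),
    ])
    clf.fit(X, np.asarray(y))
    return clf


def majority_vote(
    window_preds: Sequence[str], window_probs: np.ndarray | None = None
) -> str:
    """Most frequent range; ties broken by summed class probability, then by
    the lower range (low < medium < high)."""
    if len(window_preds) == 0:
        raise ValueError("no retained windows for participant")
    counts = {r: 0 for r in RANGE_ORDER}
    for p in window_preds:
        counts[p] += 1
    top = max(counts.values())
    tied = [r for r in RANGE_ORDER if counts[r] == top]
    if len(tied) == 1 or window_probs is None:
        return tied[0]
    sums = {
        r: float(np.sum(window_probs[:, RANGE_CODE[r]])) for r in tied
    }
    best = max(sums.values())
    return next(r for r in RANGE_ORDER if r in tied and sums[r] == best)


@dataclass
class Fold:
    train: list[str]
    validation: list[str]
    test: list[str]


def repetition_folds(participants: Sequence[str], seed: int) -> list[Fold]:
    """The fold rotation used by repetition ``seed``.

    Each repetition re-randomises the whole scheme: the participant order is
    shuffled (so block composition varies across repetitions) before the
    cyclic blocks are cut.  Matches the shuffle performed inside
    :func:`nested_cross_validation` for the same seed.
    """
    rng = np.random.default_rng(seed)
    ids = list(participants)
    rng.shuffle(ids)
    return make_folds(ids)


def make_folds(
    participants: Sequence[str], test_block: int = 5, val_block: int = 5
) -> list[Fold]:
    """Cyclic contiguous blocks: test blocks partition the cohort; the
    validation block is the stretch following the test block (wrapping)."""
    ids = list(participants)
    n = len(ids)
    folds = []
    for start in range(0, n, test_block):
        test = ids[start : start + test_block]
        after = [ids[(start + len(test) + k) % n] for k in range(val_block)]
        validation = after
        used = set(test) | set(validation)
        train = [p for p in ids if p not in used]
        folds.append(Fold(train=train, validation=validation, test=test))
    return folds


def _participant_matrix(
    table: pd.DataFrame, ids: Sequence[str], cols: np.ndarray,
    bins: TraitBins | None,
):
    sel = table[table["participant_id"].isin(set(ids))]
    X = sel.iloc[:, 4:].to_numpy()[:, cols]
    pids = sel["participant_id"].to_numpy()
    y = (np.array([bins.assignment[p] for p in pids]) if bins is not None
         else None)
    return X, y, pids, sel


def _predict_participants(
    clf: Pipeline, table: pd.DataFrame, ids: Sequence[str], cols: np.ndarray
) -> tuple[dict[str, str], pd.DataFrame]:
    X, _, pids, sel = _participant_matrix(table, ids, cols, None)
    if len(X) == 0:
        return {}, pd.DataFrame()
    preds = clf.predict(X)
    probs = clf.predict_proba(X)
    classes = list(clf.classes_)
    full_probs = np.zeros((len(X), 3))
    for k, r in enumerate(RANGE_ORDER):
        if r in classes:
            full_probs[:, k] = probs[:, classes.index(r)]
    out = {}
    for pid in ids:
        mask = pids == pid
        if mask.any():
            out[pid] = majority_vote(preds[mask].tolist(), full_probs[mask])
    wdf = sel[["participant_id", "start", "end", "context"]].copy()
    wdf["pred"] = preds
    for k, r in enumerate(RANGE_ORDER):
        wdf[f"p_{r}"] = full_probs[:, k]
    return out, wdf


@dataclass
class PredictionSet:
    """Nested-CV output for one repetition of one trait."""

    trait: str
    seed: int
    predictions: dict[str, str] = field(default_factory=dict)
    window_predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    selected: list[tuple[Candidate, float]] = field(default_factory=list)
    models: list[Pipeline] = field(default_factory=list)
    selected_columns: list[np.ndarray] = field(default_factory=list)


def nested_cross_validation(
    cohort: CohortFeatures,
    bins: TraitBins,
    spec: ForestSpec,
    candidates: Sequence[Candidate] | None = None,
    seed: int = 0,
) -> PredictionSet:
    """Full nested CV for one trait.

    Per outer fold, every candidate is trained on the training block and
    scored by participant-level macro F1 on the validation block; the winner
    (ties to the larger window, then the larger feature subset) is retrained
    on train ∪ validation and applied to the test block.
    """
    from .evaluation import macro_f1

    candidates = list(candidates) if candidates is not None else \
        default_candidates(window_sizes=sorted(cohort.tables))
    if not candidates:
        raise ValueError("empty candidate grid")
    subsets = feature_subsets()
    out = PredictionSet(trait=bins.trait, seed=seed)
    rng = np.random.default_rng(seed)
    # each repetition re-randomises block composition along with forest seeds
    ids = list(cohort.participants)
    rng.shuffle(ids)
    folds = make_folds(ids)

    for fold in folds:
        best = None  # (f1, window, subset_len, candidate)
        for cand in candidates:
            table = cohort.tables[cand.window_size]
            cols = subsets[cand.subset]
            Xtr, ytr, _, _ = _participant_matrix(table, fold.train, cols, bins)
            if len(set(ytr)) < 2:
                continue
            cspec = ForestSpec(spec.n_trees, spec.max_depth,
                               spec.max_features_per_split,
                               seed=int(rng.integers(2**31)))
            clf = fit_trait_classifier(Xtr, ytr, cspec)
            preds, _ = _predict_participants(clf, table, fold.validation, cols)
            truth = {p: bins.assignment[p] for p in preds}
            score = macro_f1(preds, truth) if preds else 0.0
            key = (score, cand.window_size, len(subsets[cand.subset]))
            if best is None or key > best[0]:
                best = (key, cand)
        if best is None:
            continue
        cand = best[1]
        table = cohort.tables[cand.window_size]
        cols = subsets[cand.subset]
        merged = fold.train + fold.validation
        Xtr, ytr, _, _ = _participant_matrix(table, merged, cols, bins)
        fspec = ForestSpec(spec.n_trees, spec.max_depth,
                           spec.max_features_per_split,
                           seed=int(rng.integers(2**31)))
        clf = fit_trait_classifier(Xtr, ytr, fspec)
        preds, wdf = _predict_participants(clf, table, fold.test, cols)
        out.predictions.update(preds)
        out.window_predictions = pd.concat(
            [out.window_predictions, wdf], ignore_index=True
        )
        out.selected.append((cand, best[0][0]))
        out.models.append(clf)
        out.selected_columns.append(cols)
    return out


@dataclass
class ImportanceTable:
    """Per-repetition forest feature importances plus summary statistics."""

    per_model: pd.DataFrame  # models × features
    summary: pd.DataFrame    # features × {median, iqr, min, max}


def feature_importances(
    models: Sequence[Pipeline],
    columns: Sequence[np.ndarray] | None = None,
) -> ImportanceTable:
    """Impurity-decrease importances averaged over trees, per fitted model.

    Importances are mapped back onto the full 207-feature inventory (features
    outside a model's selected subset, or never used in a split, get 0);
    within each model they sum to 1.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    rows = []
    for k, clf in enumerate(models):
        imp = clf.named_steps["forest"].feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        full = np.zeros(N_FEATURES)
        cols = (columns[k] if columns is not None
                else np.arange(len(imp)))
        full[cols] = imp
        rows.append(full)
    per_model = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    q1, q3 = per_model.quantile(0.25), per_model.quantile(0.75)
    summary = pd.DataFrame({
        "median": per_model.median(),
        "iqr": q3 - q1,
        "min": per_model.min(),
        "max": per_model.max(),
    })
    return ImportanceTable(per_model=per_model, summary=summary)
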