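"""Scoring, baselines, repetition machinery, reliability and correlations.

Performance is the macro-averaged F1 over the three score ranges, with the
0/0 → 0 convention for empty precision or recall denominators.  Three
baselines contextualise the classifier: a uniform-random predictor, a
most-frequent-training-range predictor, and a label-permutation run of the
full nested CV.  Repetition means carry percentile bootstrap confidence
intervals.  Reliability compares majority-vote predictions reconstructed
from different parts of the recording (split halves, way I vs II, shop vs
way), averaging per-repetition Pearson correlations through the Fisher
z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import RANGE_CODE, RANGE_ORDER, TraitBins
from .model import (
    Candidate,
    CohortFeatures,
    Fold,
    ForestSpec,
    PredictionSet,
    majority_vote,
    make_folds,
    nested_cross_validation,
    repetition_folds,
)

# ------------------------------------------------------------------ scores --

def macro_f1(pred: Mapping[str, str], truth: Mapping[str, str]) -> float:
    """Unweighted mean over the three ranges of per-range F1.

    Per-range F1 is the harmonic mean of precision and recall; empty
    denominators yield 0.
    """
    if set(pred) != set(truth):
        raise ValueError("prediction and truth cover different participants")
    f1s = []
    for r in RANGE_ORDER:
        tp = sum(1 for p in pred if pred[p] == r and truth[p] == r)
        n_pred = sum(1 for p in pred if pred[p] == r)
        n_true = sum(1 for p in truth if truth[p] == r)
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_true if n_true else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        f1s.append(f1)
    return float(np.mean(f1s))


# --------------------------------------------------------------- baselines --

def uniform_random_baseline(
    participants: Sequence[str], seed: int
) -> dict[str, str]:
    """One uniformly random range per participant."""
    rng = np.random.default_rng(seed)
    return {p: RANGE_ORDER[rng.integers(3)] for p in participants}


def most_frequent_baseline(
    folds: Sequence[Fold], bins: TraitBins
) -> dict[str, str]:
    """Per fold, predict the modal training range (ties to the lower range)
    for every test participant."""
    out: dict[str, str] = {}
    for fold in folds:
        counts = {r: 0 for r in RANGE_ORDER}
        for p in fold.train:
            counts[bins.assignment[p]] += 1
        top = max(counts.values())
        mode = next(r for r in RANGE_ORDER if counts[r] == top)
        for p in fold.test:
            out[p] = mode
    return out


def permute_bins(bins: TraitBins, seed: int) -> TraitBins:
    """Shuffle the participant → range assignment (multiset preserved)."""
    rng = np.random.default_rng(seed)
    pids = list(bins.assignment)
    values = list(bins.assignment.values())
    rng.shuffle(values)
    return TraitBins(trait=bins.trait, boundaries=bins.boundaries,
                     assignment=dict(zip(pids, values)))


def label_permutation_run(
    cohort: CohortFeatures,
    bins: TraitBins,
    spec: ForestSpec,
    candidates: Sequence[Candidate] | None = None,
    seed: int = 0,
) -> PredictionSet:
    """Nested CV with the gaze–trait link destroyed by label shuffling."""
    permuted = permute_bins(bins, seed)
    return nested_cross_validation(cohort, permuted, spec, candidates, seed)


# ----------------------------------------------------------- repetitions ---

def bootstrap_ci(
    scores: Sequence[float], iters: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI around the mean of a score list."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores for a bootstrap CI")
    if scores.max() == scores.min():  # degenerate: avoid float residue
        return float(scores[0]), float(scores[0])
    rng = np.random.default_rng(seed)
    means = rng.choice(scores, size=(iters, scores.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class EvaluationResult:
    """Repetition-level F1 scores for the classifier and all baselines."""

    trait: str
    scores: dict[str, list[float]]  # method -> per-repetition macro F1
    prediction_sets: list[PredictionSet] = field(default_factory=list)

    def mean(self, method: str) -> float:
        return float(np.mean(self.scores[method]))

    def ci(self, method: str, seed: int = 0) -> tuple[float, float]:
        return bootstrap_ci(self.scores[method], seed=seed)

    def table(self) -> pd.DataFrame:
        rows = []
        for method, vals in self.scores.items():
            lo, hi = bootstrap_ci(vals) if len(vals) >= 2 else (np.nan, np.nan)
            rows.append((self.trait, method, float(np.mean(vals)), lo, hi,
                         len(vals)))
        return pd.DataFrame(
            rows, columns=["trait", "method", "mean_f1", "ci_lo", "ci_hi",
                           "n_reps"]
        )


def evaluate_trait(
    cohort: CohortFeatures,
    bins: TraitBins,
    spec: ForestSpec,
    candidates: Sequence[Candidate] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    with_permutation: bool = True,
) -> EvaluationResult:
    """Run classifier and baselines ``n_reps`` times with distinct seeds."""
    ids = cohort.participants
    truth = {p: bins.assignment[p] for p in ids}
    scores: dict[str, list[float]] = {
        "classifier": [], "uniform_random": [], "most_frequent": [],
    }
    if with_permutation:
        scores["label_permutation"] = []
    result = EvaluationResult(trait=bins.trait, scores=scores)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    for rep_seed in rep_seeds:
        ps = nested_cross_validation(cohort, bins, spec, candidates, rep_seed)
        scores["classifier"].append(
            macro_f1(ps.predictions, {p: truth[p] for p in ps.predictions})
        )
        result.prediction_sets.append(ps)
        scores["uniform_random"].append(
            macro_f1(uniform_random_baseline(ids, rep_seed), truth)
        )
        mf = most_frequent_baseline(repetition_folds(ids, rep_seed), bins)
        scores["most_frequent"].append(macro_f1(mf, {p: truth[p] for p in mf}))
        if with_permutation:
            perm = label_permutation_run(cohort, bins, spec, candidates, rep_seed)
            scores["label_permutation"].append(
                macro_f1(perm.predictions,
                         {p: truth[p] for p in perm.predictions})
            )
    return result


# ------------------------------------------------------------- reliability --

def context_prediction(
    pred_set: PredictionSet,
    window_filter: Callable[[pd.DataFrame], pd.Series],
) -> dict[str, str]:
    """Majority vote restricted to windows passing ``window_filter``.

    Participants with no retained window in the selection are dropped.
    """
    wdf = pred_set.window_predictions
    if wdf.empty:
        return {}
    sel = wdf[window_filter(wdf)]
    out = {}
    for pid, grp in sel.groupby("participant_id"):
        probs = grp[[f"p_{r}" for r in RANGE_ORDER]].to_numpy()
        out[str(pid)] = majority_vote(grp["pred"].tolist(), probs)
    return out


def _midpoint(wdf: pd.DataFrame) -> pd.Series:
    return 0.5 * (wdf["start"] + wdf["end"])


def split_pair_filters(
    durations: Mapping[str, float]
) -> dict[str, tuple[Callable, Callable]]:
    """The three comparison pairs: split halves, way I vs II, shop vs way."""
    def first_half(wdf):
        half = wdf["participant_id"].map(durations) / 2.0
        return _midpoint(wdf) < half

    def second_half(wdf):
        half = wdf["participant_id"].map(durations) / 2.0
        return _midpoint(wdf) >= half

    return {
        "half1_half2": (first_half, second_half),
        "way1_way2": (lambda w: w["context"] == "way1",
                      lambda w: w["context"] == "way2"),
        "shop_way": (lambda w: w["context"] == "shop",
                     lambda w: w["context"].isin(["way1", "way2"])),
    }


def prediction_reliability(
    pairs: Sequence[tuple[Mapping[str, str], Mapping[str, str]]],
) -> float:
    """Fisher-averaged Pearson correlation over prediction pairs.

    Predictions are encoded ordinally (low=0, medium=1, high=2); each pair is
    correlated over its common participants; degenerate (zero-variance or
    too-small) pairs are skipped.
    """
    zs = []
    for preds_a, preds_b in pairs:
        common = sorted(set(preds_a) & set(preds_b))
        if len(common) < 3:
            continue
        a = np.array([RANGE_CODE[preds_a[p]] for p in common], dtype=float)
        b = np.array([RANGE_CODE[preds_b[p]] for p in common], dtype=float)
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        zs.append(np.arctanh(np.clip(r, -1.0, 1.0)))
    if not zs:
        raise ValueError("all prediction pairs degenerate")
    return float(np.tanh(np.mean(zs)))


def reliability_table(
    prediction_sets: Sequence[PredictionSet],
    durations: Mapping[str, float],
) -> pd.DataFrame:
    """Per comparison pair, the Fisher-averaged reliability across
    repetitions (pairing repetition i with repetition i)."""
    rows = []
    for name, (fa, fb) in split_pair_filters(durations).items():
        pairs = [
            (context_prediction(ps, fa), context_prediction(ps, fb))
            for ps in prediction_sets
        ]
        rows.append((name, prediction_reliability(pairs), len(pairs)))
    return pd.DataFrame(rows, columns=["comparison", "reliability", "n_pairs"])


# ------------------------------------------------------------ correlations --

def feature_trait_correlations(
    features_15s: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between per-participant mean features and raw trait scores.

    Features are averaged across each participant's retained windows first.
    Zero-variance features get r = 0 and a ``degenerate`` flag.
    """
    per_participant = features_15s.drop(columns=["start", "end", "context"]) \
        .groupby("participant_id").mean()
    common = per_participant.index.intersection(traits.index)
    fmat = per_participant.loc[common]
    rows = []
    for feat in fmat.columns:
        fv = fmat[feat].to_numpy(dtype=float)
        degenerate = fv.std() == 0
        for trait in traits.columns:
            tv = traits.loc[common, trait].to_numpy(dtype=float)
            if degenerate or tv.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(fv, tv)[0, 1])
            rows.append((feat, trait, r, bool(degenerate)))
    return pd.DataFrame(rows, columns=["feature", "trait", "r", "degenerate"])
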