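"""Shared fixtures: small handmade recordings and synthetic cohorts.

The two cohort fixtures are session-scoped because feature extraction over a
42-participant cohort is the expensive step shared by several end-to-end
tests.  Recordings are 4 minutes long — long enough for dozens of retained
windows per participant, short enough to keep the suite quick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazetraits.gaze_io import GazeRecording, mark_erroneous_samples
from gazetraits.labels import bin_all_traits
from gazetraits.model import build_cohort_features
from gazetraits.simulate import EffectSpec, generate_cohort

COHORT_N = 42
COHORT_DURATION = 240.0
COHORT_WINDOW_SIZES = (15.0, 30.0)


def make_recording(
    x, y, pupil=None, rate: float = 60.0, participant_id: str = "p", contexts=None
) -> GazeRecording:
    """Recording from raw arrays, marked for erroneous samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    pupil = np.full(n, 3.5) if pupil is None else np.asarray(pupil, dtype=float)
    samples = pd.DataFrame(
        {"t": np.arange(n) / rate, "x": x, "y": y, "pupil": pupil}
    )
    rec = GazeRecording(
        participant_id=participant_id, rate=rate, samples=samples,
        contexts=contexts or [],
    )
    return mark_erroneous_samples(rec)


@pytest.fixture(scope="session")
def strong_cohort():
    """n=42 cohort with extraversion shifting three oculomotor parameters."""
    recs, traits = generate_cohort(
        COHORT_N, EffectSpec.strong("extraversion"), seed=11,
        duration=COHORT_DURATION,
    )
    cf = build_cohort_features(recs, window_sizes=COHORT_WINDOW_SIZES)
    return cf, bin_all_traits(traits), traits, recs


N_REPS = 20
CANDIDATES = None  # filled lazily to avoid importing model at collection


def _candidates():
    from gazetraits.model import Candidate

    return [Candidate(15.0, "all"), Candidate(30.0, "all")]


@pytest.fixture(scope="session")
def strong_eval(strong_cohort):
    """Classifier + baselines on the strong cohort, 20 repetitions."""
    from gazetraits.evaluation import evaluate_trait
    from gazetraits.model import ForestSpec

    cf, bins, traits, _ = strong_cohort
    return evaluate_trait(
        cf, bins["extraversion"], ForestSpec(), _candidates(),
        n_reps=N_REPS, seed=101, with_permutation=True,
    )


@pytest.fixture(scope="session")
def null_eval(null_cohort):
    """Classifier + baselines on the null cohort, 20 repetitions."""
    from gazetraits.evaluation import evaluate_trait
    from gazetraits.model import ForestSpec

    cf, bins, traits, _ = null_cohort
    return evaluate_trait(
        cf, bins["extraversion"], ForestSpec(), _candidates(),
        n_reps=N_REPS, seed=202, with_permutation=True,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """n=42 cohort with no trait → oculomotor coupling."""
    recs, traits = generate_cohort(
        COHORT_N, EffectSpec.null(), seed=23, duration=COHORT_DURATION,
    )
    cf = build_cohort_features(recs, window_sizes=COHORT_WINDOW_SIZES)
    return cf, bin_all_traits(traits), traits, recs
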