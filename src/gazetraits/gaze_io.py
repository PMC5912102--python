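"""Gaze-recording data model, CSV I/O, erroneous-sample marking and participant screening.

A recording is a single (cyclopean) gaze stream sampled nominally at 60 Hz.
Coordinates are expressed in tracking-range units: the calibrated field of the
eye tracker maps to the unit square, with the origin at the top-left corner and
y increasing downward.  Pupil diameter is in millimetres and absent (NaN)
whenever the tracker lost the pupil.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Traits consumed downstream: the five NEO-FFI factors plus the two curiosity scales.
TRAITS = (
    "neuroticism",
    "extraversion",
    "openness",
    "agreeableness",
    "conscientiousness",
    "pcs",
    "cei",
)

CONTEXT_LABELS = ("way1", "shop", "way2")

#: Samples beyond 150% of the tracking range are treated as erroneous.  The
#: 150% interval is centred on the range, i.e. [-0.25, 1.25] on each axis.
RANGE_SLACK = 0.25

#: Participants with more than this share of erroneous samples are excluded.
MAX_ERRONEOUS_FRACTION = 0.5

#: Participants whose gaze stays constant on either axis for more than this
#: share of valid samples are excluded (tracker pathology, not behaviour).
MAX_CONSTANCY_FRACTION = 0.3

GAZE_COLUMNS = ("t", "x", "y", "pupil")


class GazeParseError(ValueError):
    """Raised when a gaze or context table violates the format contract."""


@dataclass
class GazeRecording:
    """One participant's gaze stream plus annotated activity contexts.

    ``samples`` holds columns ``t, x, y, pupil, valid``; ``valid`` is
    maintained by :func:`mark_erroneous_samples`.  ``contexts`` is an ordered,
    non-overlapping list of ``(label, start, end)`` segments in seconds.
    """

    participant_id: str
    rate: float
    samples: pd.DataFrame
    contexts: list[tuple[str, float, float]] = field(default_factory=list)
    ground_truth: Optional[object] = None  # set by the simulator, if any

    def __post_init__(self) -> None:
        t = self.samples["t"].to_numpy()
        if len(t) and np.any(t < 0):
            raise GazeParseError("negative timestamps")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise GazeParseError(
                f"non-monotonic timestamps at row {int(bad[0]) + 1}"
            )
        if "valid" not in self.samples.columns:
            self.samples = self.samples.assign(valid=True)
        if not self.contexts:
            self.contexts = [("way1", 0.0, self.duration)]
        self._check_contexts()

    def _check_contexts(self) -> None:
        prev_end = 0.0
        for label, start, end in self.contexts:
            if start < prev_end - 1e-9 or end < start:
                raise GazeParseError("context segments overlap or are unordered")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Recording length in seconds (last timestamp plus one sample period)."""
        t = self.samples["t"].to_numpy()
        if len(t) == 0:
            return 0.0
        return float(t[-1] - t[0] + 1.0 / self.rate)

    @property
    def erroneous_fraction(self) -> float:
        return float((~self.samples["valid"]).mean())


@dataclass
class ScreeningReport:
    participant_id: str
    erroneous_fraction: float
    constancy_fraction: float
    excluded: bool
    reason: str


def read_gaze_recording(
    path: str | Path,
    context_path: str | Path | None = None,
    participant_id: str | None = None,
    rate: float = 60.0,
) -> GazeRecording:
    """Read a gaze CSV (columns ``t,x,y,pupil``; empty pupil = not detected).

    When ``context_path`` is given it must be a CSV ``label,start,end``; else
    a single segment spanning the whole recording is attached.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeParseError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(GAZE_COLUMNS)].astype(float)
    contexts: list[tuple[str, float, float]] = []
    if context_path is not None:
        cdf = pd.read_csv(context_path, float_precision="round_trip")
        for col in ("label", "start", "end"):
            if col not in cdf.columns:
                raise GazeParseError(f"context table missing column {col!r}")
        contexts = [
            (str(r.label), float(r.start), float(r.end)) for r in cdf.itertuples()
        ]
    return GazeRecording(
        participant_id=participant_id or path.stem,
        rate=rate,
        samples=df,
        contexts=contexts,
    )


def write_gaze_recording(
    rec: GazeRecording,
    path: str | Path,
    context_path: str | Path | None = None,
) -> None:
    # %.17g keeps the roundtrip bit-exact for doubles
    rec.samples.loc[:, list(GAZE_COLUMNS)].to_csv(
        path, index=False, float_format="%.17g"
    )
    if context_path is not None:
        pd.DataFrame(rec.contexts, columns=["label", "start", "end"]).to_csv(
            context_path, index=False, float_format="%.17g"
        )


def read_trait_scores(path: str | Path) -> pd.DataFrame:
    """Read the trait table; one row per participant, all 7 traits required."""
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", *TRAITS) if c not in df.columns]
    if missing:
        raise GazeParseError(f"trait table missing column(s): {', '.join(missing)}")
    return df.set_index("participant_id")[list(TRAITS)].astype(float)


def write_trait_scores(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename_axis("participant_id").reset_index().to_csv(path, index=False)


def mark_erroneous_samples(rec: GazeRecording) -> GazeRecording:
    """Flag samples as erroneous (``valid=False``) per the tracking-range rule.

    A sample is erroneous iff the pupil was not detected or gaze lies beyond
    150% of the tracking range on either axis.  Idempotent; returns a new
    recording, samples otherwise untouched.
    """
    s = rec.samples
    lo, hi = -RANGE_SLACK, 1.0 + RANGE_SLACK
    valid = (
        s["pupil"].notna()
        & s["x"].between(lo, hi)
        & s["y"].between(lo, hi)
    ).to_numpy()
    return replace(rec, samples=s.assign(valid=valid))


def _longest_plateau_fraction(values: np.ndarray) -> float:
    """Share of the longest run of consecutive identical values."""
    if len(values) == 0:
        return 0.0
    change = np.flatnonzero(np.diff(values) != 0)
    run_edges = np.concatenate(([-1], change, [len(values) - 1]))
    return float(np.max(np.diff(run_edges)) / len(values))


def constancy_fraction(rec: GazeRecording) -> float:
    """Longest constant-gaze plateau (either axis) as a share of valid samples."""
    s = rec.samples[rec.samples["valid"]]
    return max(
        _longest_plateau_fraction(s["x"].to_numpy()),
        _longest_plateau_fraction(s["y"].to_numpy()),
    )


def screen_participants(
    cohort: Sequence[GazeRecording],
) -> tuple[list[GazeRecording], list[ScreeningReport]]:
    """Apply the cohort exclusion rules; erroneous marking must be done first.

    Excludes recordings with erroneous fraction > 0.5 or a constant-gaze
    plateau covering > 0.3 of valid samples.  A report is emitted for every
    participant, retained or not.
    """
    if not cohort:
        raise ValueError("empty cohort")
    retained: list[GazeRecording] = []
    reports: list[ScreeningReport] = []
    for rec in cohort:
        err = rec.erroneous_fraction
        const = constancy_fraction(rec)
        if err > MAX_ERRONEOUS_FRACTION:
            excluded, reason = True, "erroneous>0.5"
        elif const > MAX_CONSTANCY_FRACTION:
            excluded, reason = True, "constant-gaze"
        else:
            excluded, reason = False, "retained"
            retained.append(rec)
        reports.append(
            ScreeningReport(rec.participant_id, err, const, excluded, reason)
        )
    return retained, reports
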