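"""Oculomotor event detection: fixations (I-DT), saccades, blinks.

Fixations are found with a dispersion-threshold algorithm: consecutive samples
are grouped while their joint spatial extent, measured as
``(max x - min x) + (max y - min y)`` over valid samples, stays within 2.5% of
the tracking range, with a 100 ms minimum duration.  Every movement between
two consecutive fixations is a candidate saccade, accepted if it lasts at most
500 ms and reaches a peak velocity of at least 200% of the tracking range per
second.  Fixations and saccades containing more than 50% erroneous samples are
discarded.  Blinks are maximal runs of pupil-absent samples of physiological
duration; longer runs are treated as track loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import GazeRecording

#: Dispersion threshold: 2.5% of the tracking range width.
DISPERSION_THRESHOLD = 0.025
#: Minimum fixation duration in seconds.
MIN_FIXATION_DURATION = 0.100
#: Maximum accepted saccade duration in seconds.
MAX_SACCADE_DURATION = 0.500
#: Minimum accepted peak saccade velocity, tracking ranges per second.
MIN_SACCADE_PEAK_VELOCITY = 2.0
#: Events with more than this share of erroneous samples are discarded.
MAX_EVENT_ERRONEOUS_SHARE = 0.5
#: Physiological blink-duration band in seconds; pupil-absent runs outside
#: this band are noise (below) or track loss (above).
BLINK_BAND = (0.075, 0.500)


@dataclass
class Fixation:
    start: float
    end: float
    centroid: tuple[float, float]
    dispersion: float
    pupil_mean: float
    pupil_var: float
    erroneous_share: float
    i0: int  # first sample index
    i1: int  # last sample index (inclusive)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Saccade:
    start: float
    end: float
    amplitude: float
    direction: float  # radians, positive = upward on screen
    peak_velocity: float
    erroneous_share: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Blink:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _dispersion(x: np.ndarray, y: np.ndarray, valid: np.ndarray, i: int, j: int) -> float:
    """Spatial extent of valid samples in [i, j]; +inf when none are valid."""
    sel = valid[i : j + 1]
    if not sel.any():
        return math.inf
    xs = x[i : j + 1][sel]
    ys = y[i : j + 1][sel]
    return float((xs.max() - xs.min()) + (ys.max() - ys.min()))


def detect_fixations(rec: GazeRecording) -> list[Fixation]:
    """Dispersion-threshold fixation detection over a marked recording.

    Greedy grouping: starting from each candidate onset, the minimal group
    spanning the 100 ms duration gate is tested against the dispersion
    threshold; on success it is extended sample by sample until the threshold
    would be exceeded, emitted, and the scan resumes after it.  On failure the
    onset advances by one sample.  Groups with more than 50% erroneous samples
    are discarded (the scan still resumes after them).
    """
    s = rec.samples
    t = s["t"].to_numpy()
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    valid = s["valid"].to_numpy()
    pupil = s["pupil"].to_numpy()
    n = len(t)

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        # minimal window satisfying the duration gate
        j = i
        while j < n and t[j] - t[i] < MIN_FIXATION_DURATION:
            j += 1
        if j >= n:
            break
        if _dispersion(x, y, valid, i, j) <= DISPERSION_THRESHOLD:
            while j + 1 < n and _dispersion(x, y, valid, i, j + 1) <= DISPERSION_THRESHOLD:
                j += 1
            fix = _make_fixation(t, x, y, valid, pupil, i, j)
            if fix is not None:
                fixations.append(fix)
            i = j + 1
        else:
            i += 1
    return fixations


def _make_fixation(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    pupil: np.ndarray,
    i: int,
    j: int,
) -> Fixation | None:
    sel = valid[i : j + 1]
    err_share = float(1.0 - sel.mean())
    if err_share > MAX_EVENT_ERRONEOUS_SHARE:
        return None
    xs = x[i : j + 1][sel]
    ys = y[i : j + 1][sel]
    ps = pupil[i : j + 1][sel]
    return Fixation(
        start=float(t[i]),
        end=float(t[j]),
        centroid=(float(xs.mean()), float(ys.mean())),
        dispersion=float((xs.max() - xs.min()) + (ys.max() - ys.min())),
        pupil_mean=float(np.mean(ps)),
        pupil_var=float(np.var(ps)),
        erroneous_share=err_share,
        i0=i,
        i1=j,
    )


def sample_velocities(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Speeds between consecutive valid samples, range units per second.

    Gaps caused by erroneous samples use the actual time difference between
    the bounding valid samples.
    """
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return np.empty(0)
    dt = np.diff(t[idx])
    dist = np.hypot(np.diff(x[idx]), np.diff(y[idx]))
    return dist / dt


def detect_saccades(rec: GazeRecording, fixations: list[Fixation]) -> list[Saccade]:
    """Candidate saccades between consecutive fixations, filtered by the
    duration, peak-velocity and erroneous-share rules."""
    s = rec.samples
    t = s["t"].to_numpy()
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    valid = s["valid"].to_numpy()

    saccades: list[Saccade] = []
    for a, b in zip(fixations, fixations[1:]):
        duration = b.start - a.end
        if duration > MAX_SACCADE_DURATION:
            continue
        interior = slice(a.i1 + 1, b.i0)
        n_interior = interior.stop - interior.start
        err_share = (
            float((~valid[interior]).mean()) if n_interior > 0 else 0.0
        )
        if err_share > MAX_EVENT_ERRONEOUS_SHARE:
            continue
        # velocity over the gap, including the bounding fixation samples so an
        # empty interior still has a defined speed
        span = slice(a.i1, b.i0 + 1)
        v = sample_velocities(t[span], x[span], y[span], valid[span])
        peak = float(v.max()) if v.size else 0.0
        if peak < MIN_SACCADE_PEAK_VELOCITY:
            continue
        dx = b.centroid[0] - a.centroid[0]
        dy = b.centroid[1] - a.centroid[1]
        saccades.append(
            Saccade(
                start=float(a.end),
                end=float(b.start),
                amplitude=float(math.hypot(dx, dy)),
                direction=float(math.atan2(-dy, dx)),  # screen y points down
                peak_velocity=peak,
                erroneous_share=err_share,
            )
        )
    return saccades


def detect_blinks(rec: GazeRecording) -> list[Blink]:
    """Maximal pupil-absent runs whose duration falls in the blink band."""
    s = rec.samples
    t = s["t"].to_numpy()
    absent = s["pupil"].isna().to_numpy()
    if not absent.any():
        return []
    dt = 1.0 / rec.rate
    padded = np.concatenate(([False], absent, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]  # stop is exclusive
    blinks = []
    lo, hi = BLINK_BAND
    for i0, i1 in zip(starts, stops):
        duration = t[i1 - 1] - t[i0] + dt
        if lo <= duration <= hi:
            blinks.append(Blink(start=float(t[i0]), end=float(t[i0] + duration)))
    return blinks


def events_to_frame(
    fixations: list[Fixation], saccades: list[Saccade], blinks: list[Blink]
) -> pd.DataFrame:
    """Flat CSV-ready inventory of all detected events."""
    rows = []
    for f in fixations:
        rows.append(
            dict(type="fixation", start=f.start, end=f.end, x=f.centroid[0],
                 y=f.centroid[1], dispersion=f.dispersion,
                 pupil_mean=f.pupil_mean, pupil_var=f.pupil_var,
                 erroneous_share=f.erroneous_share)
        )
    for sc in saccades:
        rows.append(
            dict(type="saccade", start=sc.start, end=sc.end,
                 amplitude=sc.amplitude, direction=sc.direction,
                 peak_velocity=sc.peak_velocity,
                 erroneous_share=sc.erroneous_share)
        )
    for b in blinks:
        rows.append(dict(type="blink", start=b.start, end=b.end))
    df = pd.DataFrame(rows)
    return df.sort_values("start").reset_index(drop=True) if len(df) else df
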