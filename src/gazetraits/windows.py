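"""Sliding windows over a recording, with the retention rules.

Windows are half-open ``[start, start + size)``, advance by half the window
size (50% overlap) and are discarded when they contain more than 50%
erroneous samples, fewer than 2 valid samples, or no fixation or saccade at
all.  An event belongs to the window containing its midpoint, which prevents
double counting across the overlap.  Each window carries the context label
covering the majority of its time span (ties go to the earlier context).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .events import Blink, Fixation, Saccade
from .gaze_io import GazeRecording

MAX_WINDOW_ERRONEOUS_SHARE = 0.5
MIN_VALID_SAMPLES = 2


@dataclass
class Window:
    start: float
    end: float
    i0: int  # first sample index in the window
    i1: int  # one past the last sample index
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)
    erroneous_share: float = 0.0
    n_valid: int = 0
    context: str = ""
    discard_reasons: tuple[str, ...] = ()

    @property
    def size(self) -> float:
        return self.end - self.start

    @property
    def retained(self) -> bool:
        return not self.discard_reasons

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _majority_context(rec: GazeRecording, start: float, end: float) -> str:
    best_label, best_overlap = "", -1.0
    for label, c0, c1 in rec.contexts:
        overlap = min(end, c1) - max(start, c0)
        if overlap > best_overlap + 1e-12:  # ties keep the earlier context
            best_label, best_overlap = label, overlap
    return best_label


def candidate_windows(
    rec: GazeRecording,
    fixations: list[Fixation],
    saccades: list[Saccade],
    blinks: list[Blink],
    size: float,
) -> list[Window]:
    """All sliding-window candidates with their retention flags."""
    if size <= 0:
        raise ValueError("window size must be positive")
    t = rec.samples["t"].to_numpy()
    valid = rec.samples["valid"].to_numpy()
    duration = rec.duration
    t0 = float(t[0]) if len(t) else 0.0

    fix_mid = [f.midpoint for f in fixations]
    sac_mid = [s.midpoint for s in saccades]
    blk_mid = [b.midpoint for b in blinks]

    out: list[Window] = []
    start = t0
    step = size / 2.0
    while start + size <= t0 + duration + 1e-9:
        end = start + size
        i0 = int(np.searchsorted(t, start - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, end - 1e-12, side="left"))
        w = Window(start=start, end=end, i0=i0, i1=i1)
        w.fixations = fixations[
            bisect.bisect_left(fix_mid, start) : bisect.bisect_left(fix_mid, end)
        ]
        w.saccades = saccades[
            bisect.bisect_left(sac_mid, start) : bisect.bisect_left(sac_mid, end)
        ]
        w.blinks = blinks[
            bisect.bisect_left(blk_mid, start) : bisect.bisect_left(blk_mid, end)
        ]
        v = valid[i0:i1]
        w.n_valid = int(v.sum())
        w.erroneous_share = float(1.0 - v.mean()) if v.size else 1.0
        w.context = _majority_context(rec, start, end)
        reasons = []
        if w.erroneous_share > MAX_WINDOW_ERRONEOUS_SHARE:
            reasons.append("erroneous>0.5")
        if w.n_valid < MIN_VALID_SAMPLES:
            reasons.append("too-few-valid")
        if not w.fixations and not w.saccades:
            reasons.append("no-event")
        w.discard_reasons = tuple(reasons)
        out.append(w)
        start += step
    return out


def slide_windows(
    rec: GazeRecording,
    fixations: list[Fixation],
    saccades: list[Saccade],
    blinks: list[Blink],
    size: float,
) -> list[Window]:
    """Retained windows only (candidates surviving all discard rules)."""
    return [w for w in candidate_windows(rec, fixations, saccades, blinks, size)
            if w.retained]
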