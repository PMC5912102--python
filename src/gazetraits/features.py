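"""The 207-dimensional per-window feature bank.

Four families, concatenated in a fixed order:

* raw-gaze statistics (34): eight summary statistics for each of x, y,
  sample speed and sample acceleration, plus the valid-sample fraction and
  the x–y Pearson correlation;
* heatmap (64): an 8×8 normalized histogram of gaze points inside the
  window's central 95% interval per axis, cells enumerated row-major from
  the top-left corner;
* event statistics (53): fixation, saccade, blink and pupil summaries;
* n-gram features (56): for two event encodings (saccade-only, 16 symbols;
  fixation+saccade interleaved, 18 symbols) and n = 1..4, seven summaries of
  the n-gram histogram.

Degenerate statistics (empty event sets, constant signals) are 0 by
convention so every retained window yields a finite vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import sample_velocities
from .gaze_io import GazeRecording
from .windows import Window

N_FEATURES = 207

#: Amplitude above which a saccade counts as "large" (range units).
LARGE_SACCADE_AMPLITUDE = 0.1
#: Duration at or above which a fixation counts as "long" (s).
LONG_FIXATION_DURATION = 0.3
#: Cap for the large-to-small saccade count ratio.
AMPLITUDE_RATIO_CAP = 10.0

N_DIRECTION_BINS = 8
_STAT_NAMES = ("min", "max", "mean", "std", "median", "range", "iqr", "skew")


# ---------------------------------------------------------------- raw gaze --

def _summary_stats(v: np.ndarray) -> list[float]:
    """min,max,mean,std,median,range,IQR,skewness; zeros when undefined."""
    if v.size == 0:
        return [0.0] * 8
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:  # constant signal: exact zeros, no float residue
        return [lo, hi, lo, 0.0, lo, 0.0, 0.0, 0.0]
    std = float(v.std())
    if v.size < 2 or std == 0.0:
        skew = 0.0
    else:
        skew = float(sps.skew(v))
        if not math.isfinite(skew):
            skew = 0.0
    q75, q25 = np.percentile(v, [75, 25])
    return [lo, hi, float(v.mean()), std, float(np.median(v)),
            hi - lo, float(q75 - q25), skew]


def raw_gaze_features(rec: GazeRecording, w: Window) -> np.ndarray:
    s = rec.samples.iloc[w.i0 : w.i1]
    t = s["t"].to_numpy()
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    valid = s["valid"].to_numpy()
    xv, yv = x[valid], y[valid]

    speed = sample_velocities(t, x, y, valid)
    if speed.size >= 2:
        tv = t[valid]
        mid = 0.5 * (tv[1:] + tv[:-1])
        accel = np.diff(speed) / np.diff(mid)
    else:
        accel = np.empty(0)

    out = []
    for sig in (xv, yv, speed, accel):
        out.extend(_summary_stats(np.asarray(sig, dtype=float)))
    out.append(float(valid.mean()) if valid.size else 0.0)
    if xv.size >= 2 and np.ptp(xv) > 0 and np.ptp(yv) > 0:
        out.append(float(np.corrcoef(xv, yv)[0, 1]))
    else:
        out.append(0.0)
    return np.asarray(out)


# ----------------------------------------------------------------- heatmap --

def heatmap_features(rec: GazeRecording, w: Window) -> np.ndarray:
    """8×8 gaze heatmap over the window's central 95% interval per axis."""
    s = rec.samples.iloc[w.i0 : w.i1]
    valid = s["valid"].to_numpy()
    x = s["x"].to_numpy()[valid]
    y = s["y"].to_numpy()[valid]
    grid = np.zeros((8, 8))
    if x.size == 0:
        return np.full(64, 1.0 / 64.0)
    x_lo, x_hi = np.percentile(x, [2.5, 97.5])
    y_lo, y_hi = np.percentile(y, [2.5, 97.5])
    inside = (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi)
    xs, ys = x[inside], y[inside]
    if xs.size == 0:
        return np.full(64, 1.0 / 64.0)

    def bins(v, lo, hi):
        if hi <= lo:  # degenerate interval: all mass in row/column 0
            return np.zeros(v.size, dtype=int)
        return np.clip(((v - lo) / (hi - lo) * 8).astype(int), 0, 7)

    cols = bins(xs, x_lo, x_hi)
    rows = bins(ys, y_lo, y_hi)  # y grows downward, so row 0 is the top
    np.add.at(grid, (rows, cols), 1.0)
    return (grid / grid.sum()).ravel()


# ------------------------------------------------------------------ events --

def _stats4(v: list[float]) -> list[float]:
    a = np.asarray(v, dtype=float)
    if a.size == 0:
        return [0.0] * 4
    return [float(a.min()), float(a.max()), float(a.mean()), float(a.std())]


def _stats5(v: list[float]) -> list[float]:
    a = np.asarray(v, dtype=float)
    if a.size == 0:
        return [0.0] * 5
    return [float(a.min()), float(a.max()), float(a.mean()), float(a.std()),
            float(np.median(a))]


def direction_bin(direction: float) -> int:
    """45° sectors centred on the 8 compass directions; 0 = right, 2 = up."""
    return int(np.round(direction / (math.pi / 4))) % N_DIRECTION_BINS


def event_features(rec: GazeRecording, w: Window) -> np.ndarray:
    s = rec.samples.iloc[w.i0 : w.i1]
    t = s["t"].to_numpy()
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    valid = s["valid"].to_numpy()
    size = w.size

    out: list[float] = []

    # fixations (15)
    fd = [f.duration for f in w.fixations]
    fdisp = [f.dispersion for f in w.fixations]
    out.append(float(len(w.fixations)))
    out.append(len(w.fixations) / size)
    out.extend(_stats5(fd))
    out.extend(_stats5(fdisp))
    out.append(float(np.sum(fd)) / size)
    in_fix_speeds = []
    for f in w.fixations:
        lo = max(f.i0, w.i0) - w.i0
        hi = min(f.i1, w.i1 - 1) - w.i0
        if hi > lo:
            v = sample_velocities(t[lo : hi + 1], x[lo : hi + 1],
                                  y[lo : hi + 1], valid[lo : hi + 1])
            in_fix_speeds.extend(v.tolist())
    a = np.asarray(in_fix_speeds)
    out.append(float(a.mean()) if a.size else 0.0)
    out.append(float(a.std()) if a.size else 0.0)

    # saccades (24)
    out.append(float(len(w.saccades)))
    out.append(len(w.saccades) / size)
    out.extend(_stats4([sc.duration for sc in w.saccades]))
    out.extend(_stats4([sc.amplitude for sc in w.saccades]))
    out.extend(_stats4([sc.peak_velocity for sc in w.saccades]))
    hist = np.zeros(N_DIRECTION_BINS)
    for sc in w.saccades:
        hist[direction_bin(sc.direction)] += 1
    out.extend((hist / hist.sum()).tolist() if hist.sum() else hist.tolist())
    n_large = sum(sc.amplitude >= LARGE_SACCADE_AMPLITUDE for sc in w.saccades)
    n_small = len(w.saccades) - n_large
    if len(w.saccades) == 0:
        ratio = 0.0
    elif n_small == 0:
        ratio = AMPLITUDE_RATIO_CAP
    else:
        ratio = min(n_large / n_small, AMPLITUDE_RATIO_CAP)
    out.append(ratio)
    out.append(float(np.sum([sc.duration for sc in w.saccades])) / size)

    # blinks (6)
    out.append(float(len(w.blinks)))
    out.append(len(w.blinks) / size * 60.0)
    out.extend(_stats4([b.duration for b in w.blinks]))

    # pupil (8)
    pv = s["pupil"].to_numpy()[valid]
    out.extend(_stats4(pv.tolist()))
    fix_pm = [f.pupil_mean for f in w.fixations]
    fix_pvar = [f.pupil_var for f in w.fixations]
    for arr in (fix_pm, fix_pvar):
        a = np.asarray(arr)
        out.append(float(a.mean()) if a.size else 0.0)
        out.append(float(a.std()) if a.size else 0.0)

    return np.asarray(out)


# ----------------------------------------------------------------- n-grams --

@dataclass(frozen=True)
class NGramConfig:
    """Alphabets for the sequence encodings.

    Encoding A: 16 saccade symbols — 8 direction bins × {large, small}.
    Encoding B: 18 symbols — A's 16 plus {short fixation, long fixation}.
    """

    large_amplitude: float = LARGE_SACCADE_AMPLITUDE
    long_duration: float = LONG_FIXATION_DURATION
    ns: tuple[int, ...] = (1, 2, 3, 4)

    @property
    def alphabet_a(self) -> int:
        return 2 * N_DIRECTION_BINS

    @property
    def alphabet_b(self) -> int:
        return 2 * N_DIRECTION_BINS + 2


def saccade_symbol(sc, cfg: NGramConfig = NGramConfig()) -> int:
    """Symbol = direction bin × 2 + (0 if large else 1)."""
    large = sc.amplitude >= cfg.large_amplitude
    return direction_bin(sc.direction) * 2 + (0 if large else 1)


def fixation_symbol(f, cfg: NGramConfig = NGramConfig()) -> int:
    """16 = short fixation, 17 = long fixation."""
    return 16 + (1 if f.duration >= cfg.long_duration else 0)


def encode_sequences(w: Window, cfg: NGramConfig) -> tuple[list[int], list[int]]:
    """(encoding-A sequence, encoding-B sequence) for one window."""
    seq_a = [saccade_symbol(sc, cfg) for sc in w.saccades]
    merged = sorted(
        [(f.midpoint, fixation_symbol(f, cfg)) for f in w.fixations]
        + [(sc.midpoint, saccade_symbol(sc, cfg)) for sc in w.saccades]
    )
    seq_b = [sym for _, sym in merged]
    return seq_a, seq_b


def ngram_histogram_features(seq: list[int], n: int, alphabet: int) -> list[float]:
    """Seven summaries of the n-gram histogram of one symbol sequence.

    distinct count, max, min, mean, variance over the non-zero entries, and
    the lexicographic indices of the most and least frequent n-gram (ties to
    the smallest index; −1 when the sequence is shorter than n).
    """
    if len(seq) < n:
        return [0.0] * 5 + [-1.0, -1.0]
    counts: dict[int, int] = {}
    for k in range(len(seq) - n + 1):
        idx = 0
        for sym in seq[k : k + n]:
            idx = idx * alphabet + sym
        counts[idx] = counts.get(idx, 0) + 1
    entries = np.asarray(list(counts.values()), dtype=float)
    indices = np.asarray(list(counts.keys()))
    order_max = indices[entries == entries.max()].min()
    order_min = indices[entries == entries.min()].min()
    return [
        float(len(counts)),
        float(entries.max()),
        float(entries.min()),
        float(entries.mean()),
        float(entries.var()),
        float(order_max),
        float(order_min),
    ]


def ngram_features(w: Window, cfg: NGramConfig = NGramConfig()) -> np.ndarray:
    seq_a, seq_b = encode_sequences(w, cfg)
    out: list[float] = []
    for seq, alphabet in ((seq_a, cfg.alphabet_a), (seq_b, cfg.alphabet_b)):
        for n in cfg.ns:
            out.extend(ngram_histogram_features(seq, n, alphabet))
    return np.asarray(out)


# ------------------------------------------------------------ full vector --

def _build_feature_names() -> list[str]:
    names = []
    for sig in ("x", "y", "speed", "accel"):
        names += [f"raw_{sig}_{st}" for st in _STAT_NAMES]
    names += ["raw_valid_fraction", "raw_xy_corr"]
    names += [f"heatmap_{i:02d}" for i in range(64)]
    names += ["fix_count", "fix_rate"]
    names += [f"fix_dur_{st}" for st in ("min", "max", "mean", "std", "median")]
    names += [f"fix_disp_{st}" for st in ("min", "max", "mean", "std", "median")]
    names += ["fix_time_fraction", "fix_speed_mean", "fix_speed_std"]
    names += ["sacc_count", "sacc_rate"]
    names += [f"sacc_dur_{st}" for st in ("min", "max", "mean", "std")]
    names += [f"sacc_amp_{st}" for st in ("min", "max", "mean", "std")]
    names += [f"sacc_pv_{st}" for st in ("min", "max", "mean", "std")]
    names += [f"sacc_dir_hist_{i}" for i in range(8)]
    names += ["sacc_large_small_ratio", "sacc_time_fraction"]
    names += ["blink_count", "blink_rate_per_min"]
    names += [f"blink_dur_{st}" for st in ("min", "max", "mean", "std")]
    names += [f"pupil_{st}" for st in ("min", "max", "mean", "std")]
    names += ["fix_pupil_mean_mean", "fix_pupil_mean_std",
              "fix_pupil_var_mean", "fix_pupil_var_std"]
    for enc in ("A", "B"):
        for n in (1, 2, 3, 4):
            for st in ("distinct", "max", "min", "mean", "var",
                       "argmax", "argmin"):
                names.append(f"ngram{enc}_n{n}_{st}")
    assert len(names) == N_FEATURES
    return names


#: Canonical feature inventory; position of each name is fixed.
FEATURE_NAMES: tuple[str, ...] = tuple(_build_feature_names())
FEATURE_INDEX: dict[str, int] = {n: i for i, n in enumerate(FEATURE_NAMES)}

#: Index arrays for the four feature families (plus complements, used as
#: candidate feature subsets during model selection).
FEATURE_FAMILIES: dict[str, np.ndarray] = {
    "raw": np.arange(0, 34),
    "heatmap": np.arange(34, 98),
    "event": np.arange(98, 151),
    "ngram": np.arange(151, 207),
}


def feature_subsets() -> dict[str, np.ndarray]:
    """All-features, each family alone, and all-minus-each-family."""
    subsets = {"all": np.arange(N_FEATURES)}
    for name, idx in FEATURE_FAMILIES.items():
        subsets[name] = idx
        subsets[f"no_{name}"] = np.setdiff1d(np.arange(N_FEATURES), idx)
    return subsets


def extract_feature_vector(rec: GazeRecording, w: Window) -> np.ndarray:
    """Concatenated 207-feature vector for one retained window."""
    vec = np.concatenate([
        raw_gaze_features(rec, w),
        heatmap_features(rec, w),
        event_features(rec, w),
        ngram_features(w),
    ])
    assert vec.shape == (N_FEATURES,)
    return vec


def feature_table(rec: GazeRecording, windows: list[Window]) -> pd.DataFrame:
    """One row per retained window: metadata columns plus the 207 features."""
    rows = []
    meta = []
    for w in windows:
        if not w.retained:
            continue
        rows.append(extract_feature_vector(rec, w))
        meta.append((rec.participant_id, w.start, w.end, w.context))
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "start", "end", "context", *FEATURE_NAMES]
        )
    df = pd.DataFrame(
        meta, columns=["participant_id", "start", "end", "context"]
    )
    return pd.concat(
        [df, pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))], axis=1
    )
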