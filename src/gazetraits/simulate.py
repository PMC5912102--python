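"""Synthetic gaze cohorts with the statistical structure the pipeline assumes.

Recordings alternate fixations (a centroid plus Gaussian jitter well inside
the dispersion threshold) and saccades (minimum-jerk transitions whose peak
velocity clears the acceptance threshold), overlaid with Poisson blinks,
additional track-loss runs up to a target loss fraction, and a slowly drifting
pupil signal.  Trait scores are Gaussian; an :class:`EffectSpec` can couple
traits to oculomotor parameters so that downstream classifiers have a real
signal to recover.  The generator's own event plan is attached to each
recording as ground truth so detector recall and precision are measurable.

Defaults emulate the everyday-errand setting the pipeline targets: 12.51 min
recordings at 60 Hz with ~19.6% track loss and a way/shop/way context split
of 40/20/40% of the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_io import TRAITS, GazeRecording, mark_erroneous_samples

#: Default recording length (s): 12.51 minutes.
DEFAULT_DURATION = 750.6
DEFAULT_RATE = 60.0


@dataclass
class OculomotorParams:
    """Per-participant generative parameters.

    Durations and amplitudes are log-normal (parametrised by their mean and
    SD on the natural scale); saccade directions are von Mises around a bias
    direction; blinks arrive as a Poisson process.
    """

    fix_dur_mean: float = 0.28   # s
    fix_dur_sd: float = 0.12     # s
    fix_jitter_sd: float = 0.0015  # range units; keeps dispersion < 0.025
    sacc_amp_mean: float = 0.11  # range units
    sacc_amp_sd: float = 0.06    # range units
    sacc_dir_bias: float = 0.0   # radians; 0 = rightward
    sacc_dir_kappa: float = 0.4  # von Mises concentration (0 = uniform)
    blink_rate: float = 12.0     # events / min
    blink_dur_mean: float = 0.15  # s
    pupil_base: float = 3.8      # mm
    pupil_sd: float = 0.25       # mm (slow drift SD)
    loss_fraction: float = 0.196  # target share of pupil-absent samples

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("sacc_dir_bias",):
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        if not 0 <= self.loss_fraction < 0.95:
            raise ValueError("loss_fraction out of range")


#: Nominal between-participant SD of each modulable parameter; EffectSpec
#: slopes are expressed in these units per trait SD.
PARAM_SD: dict[str, float] = {
    "fix_dur_mean": 0.05,
    "fix_dur_sd": 0.03,
    "fix_jitter_sd": 0.0004,
    "sacc_amp_mean": 0.025,
    "sacc_amp_sd": 0.015,
    "sacc_dir_kappa": 0.2,
    "blink_rate": 4.0,
    "blink_dur_mean": 0.03,
    "pupil_base": 0.35,
    "pupil_sd": 0.08,
    "loss_fraction": 0.04,
}

#: Hard floors keeping modulated parameters physically admissible.
_PARAM_FLOOR: dict[str, float] = {
    "fix_dur_mean": 0.12,
    "fix_dur_sd": 0.02,
    "fix_jitter_sd": 0.0005,
    "sacc_amp_mean": 0.03,
    "sacc_amp_sd": 0.005,
    "sacc_dir_kappa": 0.0,
    "blink_rate": 1.0,
    "blink_dur_mean": 0.09,
    "pupil_base": 2.0,
    "pupil_sd": 0.02,
    "loss_fraction": 0.01,
}


@dataclass
class EffectSpec:
    """Trait → oculomotor-parameter coupling.

    ``slopes[trait][param]`` is the shift of ``param`` (in units of
    ``PARAM_SD[param]``) per SD of the trait score.  ``noise_scale`` adds
    trait-independent between-participant parameter variation in the same
    units.  A zero EffectSpec leaves recordings statistically independent of
    traits.
    """

    slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_scale: float = 0.5

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(slopes={}, noise_scale=0.5)

    @classmethod
    def strong(cls, trait: str = "extraversion") -> "EffectSpec":
        """One trait shifting three oculomotor parameters by 1 SD per trait SD."""
        return cls(
            slopes={
                trait: {
                    "fix_dur_mean": 1.0,
                    "sacc_amp_mean": 1.0,
                    "blink_rate": 1.0,
                }
            },
            noise_scale=0.25,
        )


#: Default synthetic questionnaire scales (mean, SD) per trait.
TRAIT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "neuroticism": (22.0, 7.0),
    "extraversion": (29.0, 6.5),
    "openness": (27.0, 6.0),
    "agreeableness": (33.0, 6.0),
    "conscientiousness": (31.0, 7.0),
    "pcs": (50.0, 9.0),
    "cei": (31.0, 7.0),
}


def sample_traits(
    n: int,
    seed: int,
    distributions: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Draw i.i.d. Gaussian trait scores for ``n`` participants."""
    if n < 3:
        raise ValueError("need at least 3 participants for tertile binning")
    dists = dict(TRAIT_DISTRIBUTIONS)
    if distributions:
        dists.update(distributions)
    rng = np.random.default_rng(seed)
    ids = [f"p{i:03d}" for i in range(n)]
    data = {
        trait: rng.normal(dists[trait][0], dists[trait][1], size=n)
        for trait in TRAITS
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="participant_id"))


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Log-normal draws parametrised by natural-scale mean and SD."""
    if sd <= 0:
        return np.full(size, mean) if size else mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


@dataclass
class GroundTruth:
    """The generator's own event plan, for detector recall/precision checks."""

    fixations: pd.DataFrame  # start, end, x, y
    saccades: pd.DataFrame   # start, end, amplitude, direction
    blinks: pd.DataFrame     # start, end


def generate_recording(
    params: OculomotorParams,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    participant_id: str = "sim",
) -> GazeRecording:
    """Simulate one recording; erroneous marking is already applied.

    Context segments cover 40% (way1) / 20% (shop) / 40% (way2) of the
    duration.  The returned recording carries a :class:`GroundTruth` in
    ``ground_truth``.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.empty(n)
    y = np.empty(n)

    # --- event plan: alternating fixations and minimum-jerk saccades -------
    fix_rows, sacc_rows = [], []
    pos = np.array([0.5, 0.5]) + rng.normal(0, 0.1, 2)
    pos = np.clip(pos, 0.1, 0.9)
    now = 0.0
    jitter = params.fix_jitter_sd
    while now < duration:
        fdur = float(np.clip(_lognormal(rng, params.fix_dur_mean, params.fix_dur_sd),
                             0.08, 2.5))
        f_end = min(now + fdur, duration)
        i0, i1 = int(math.ceil(now * rate)), int(math.ceil(f_end * rate))
        if i1 > i0:
            x[i0:i1] = pos[0] + rng.normal(0, jitter, i1 - i0)
            y[i0:i1] = pos[1] + rng.normal(0, jitter, i1 - i0)
        fix_rows.append((now, f_end, pos[0], pos[1]))
        now = f_end
        if now >= duration:
            break
        # saccade to the next fixation location
        amp = float(np.clip(_lognormal(rng, params.sacc_amp_mean, params.sacc_amp_sd),
                            0.03, 0.6))
        direction = float(rng.vonmises(params.sacc_dir_bias, params.sacc_dir_kappa)
                          if params.sacc_dir_kappa > 0
                          else rng.uniform(-math.pi, math.pi))
        step = amp * np.array([math.cos(direction), -math.sin(direction)])
        target = pos + step
        # reflect at the borders to stay inside the tracking range
        target = np.where(target < 0.05, 0.10 - target, target)
        target = np.where(target > 0.95, 1.90 - target, target)
        target = np.clip(target, 0.05, 0.95)
        sdur = float(np.clip(0.020 + 0.10 * amp, 1.5 / rate, 0.1))
        s_end = min(now + sdur, duration)
        i0, i1 = int(math.ceil(now * rate)), int(math.ceil(s_end * rate))
        if i1 > i0:
            tau = (t[i0:i1] - now) / sdur
            shape = 10 * tau**3 - 15 * tau**4 + 6 * tau**5  # minimum jerk
            x[i0:i1] = pos[0] + (target[0] - pos[0]) * shape
            y[i0:i1] = pos[1] + (target[1] - pos[1]) * shape
        sacc_rows.append((now, s_end, float(np.hypot(*(target - pos))), direction))
        pos = target
        now = s_end

    # --- pupil: base + AR(1) drift + measurement noise ----------------------
    phi = 0.995
    drift = np.empty(n)
    eta = rng.normal(0, params.pupil_sd * math.sqrt(1 - phi**2), n)
    drift[0] = rng.normal(0, params.pupil_sd)
    for k in range(1, n):
        drift[k] = phi * drift[k - 1] + eta[k]
    pupil = params.pupil_base + drift + rng.normal(0, 0.03, n)

    # --- blinks and track loss as pupil-absent runs -------------------------
    absent = np.zeros(n, dtype=bool)
    blink_rows = []
    n_blinks = rng.poisson(params.blink_rate * duration / 60.0)
    for start in np.sort(rng.uniform(0, duration, n_blinks)):
        bdur = float(np.clip(rng.normal(params.blink_dur_mean, 0.03), 0.09, 0.45))
        i0, i1 = int(start * rate), min(int((start + bdur) * rate) + 1, n)
        absent[i0:i1] = True
        blink_rows.append((start, start + bdur))
    target_absent = int(round(params.loss_fraction * n))
    guard = 0
    while absent.sum() < target_absent and guard < 100000:
        guard += 1
        run = int(np.clip(_lognormal(rng, 1.5, 1.0), 0.6, 8.0) * rate)
        i0 = rng.integers(0, max(n - run, 1))
        deficit = target_absent - int(absent.sum())
        new = np.flatnonzero(~absent[i0 : i0 + run])
        if new.size > deficit:  # trim the last run to land on the target
            absent[i0 + new[:deficit]] = True
        else:
            absent[i0 : i0 + run] = True
    pupil[absent] = np.nan
    # during lost tracking the reported gaze freezes at its last position
    lost = np.flatnonzero(absent)
    if lost.size:
        keep = np.where(absent, np.nan, np.arange(n, dtype=float))
        last = pd.Series(keep).ffill().bfill().to_numpy().astype(int)
        x[lost] = x[last[lost]]
        y[lost] = y[last[lost]]

    contexts = [
        ("way1", 0.0, 0.4 * duration),
        ("shop", 0.4 * duration, 0.6 * duration),
        ("way2", 0.6 * duration, duration),
    ]
    samples = pd.DataFrame({"t": t, "x": x, "y": y, "pupil": pupil})
    rec = GazeRecording(
        participant_id=participant_id, rate=rate, samples=samples,
        contexts=contexts,
    )
    rec = mark_erroneous_samples(rec)
    rec.ground_truth = GroundTruth(
        fixations=pd.DataFrame(fix_rows, columns=["start", "end", "x", "y"]),
        saccades=pd.DataFrame(
            sacc_rows, columns=["start", "end", "amplitude", "direction"]
        ),
        blinks=pd.DataFrame(blink_rows, columns=["start", "end"]),
    )
    return rec


def participant_params(
    base: OculomotorParams,
    trait_z: Mapping[str, float],
    effects: EffectSpec,
    rng: np.random.Generator,
) -> OculomotorParams:
    """Baseline parameters shifted by trait effects plus independent noise."""
    shifts = {p: 0.0 for p in PARAM_SD}
    for trait, slopes in effects.slopes.items():
        z = trait_z[trait]
        for param, slope in slopes.items():
            shifts[param] += slope * z * PARAM_SD[param]
    if effects.noise_scale > 0:
        for param in PARAM_SD:
            shifts[param] += effects.noise_scale * PARAM_SD[param] * rng.normal()
    out = {}
    for param, shift in shifts.items():
        value = getattr(base, param) + shift
        out[param] = max(value, _PARAM_FLOOR[param])
    out["loss_fraction"] = min(out["loss_fraction"], 0.45)
    return replace(base, **out)


def generate_cohort(
    n: int,
    effects: EffectSpec,
    seed: int,
    base: OculomotorParams | None = None,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
) -> tuple[list[GazeRecording], pd.DataFrame]:
    """Traits plus one recording per participant, fully seed-reproducible."""
    if n < 3:
        raise ValueError("need at least 3 participants")
    base = base or OculomotorParams()
    traits = sample_traits(n, seed)
    z = (traits - traits.mean()) / traits.std(ddof=0)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n + 1)
    param_rng = np.random.default_rng(child_seeds[0])
    recordings = []
    for k, pid in enumerate(traits.index):
        params = participant_params(base, z.loc[pid], effects, param_rng)
        rec_seed = int(child_seeds[k + 1].generate_state(1)[0] % (2**31))
        recordings.append(
            generate_recording(params, duration, rate, rec_seed, participant_id=pid)
        )
    return recordings, traits


def fixation_recall(rec: GazeRecording, detected: Sequence) -> float:
    """Detector recall of the recoverable ground-truth fixations.

    Recoverable means ≥150 ms long with at most 50% erroneous samples (a
    fixation swallowed by track loss is discarded by design, not missed).  A
    truth fixation counts as recovered when some detected fixation's midpoint
    falls inside it.
    """
    truth: GroundTruth = rec.ground_truth
    t = rec.samples["t"].to_numpy()
    valid = rec.samples["valid"].to_numpy()
    tf = truth.fixations
    tf = tf[(tf["end"] - tf["start"]) >= 0.15]
    mids = np.array([f.midpoint for f in detected])
    hit = total = 0
    for row in tf.itertuples():
        sel = valid[np.searchsorted(t, row.start) : np.searchsorted(t, row.end)]
        if sel.size == 0 or sel.mean() < 0.5:
            continue
        total += 1
        if mids.size and np.any((mids >= row.start) & (mids <= row.end)):
            hit += 1
    return hit / total if total else float("nan")
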