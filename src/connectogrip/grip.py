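"""Hand-grip performance measures from 3-axis digit force recordings.

A precision-grip trial records thumb and index forces against two parallel
grip surfaces at a fixed sampling rate, together with the on-screen cue
times.  Five performance measures are extracted:

* **strength** — peak grip force during a maximum-grip trial (N);
* **reaction time** — grip cue to grip initiation, initiation defined as the
  first time the grip force rises more than 3 SD above the pre-cue baseline
  and stays there for a short sustain window (s);
* **relaxation time** — rest cue to grip termination, termination defined as
  the force returning to within 3 SD of baseline, sustained (s);
* **force magnitude control** — absolute difference between the 4 N target
  and the mean grip force over the hold window (N);
* **force direction control** — mean angular deviation of each digit's force
  vector from the surface normal over the hold window (degrees).

Repetitions are averaged per hand, and each measure is normalized as the
paretic value divided by the sum over both hands, giving five dimensionless
ratios in [0, 1] where 0.5 means symmetric performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

logger = logging.getLogger(__name__)

DIGITS = ("thumb", "index")
HANDS = ("paretic", "nonparetic")
TRIAL_KINDS = ("max_grip", "target_grip")
#: measure keys, fixed order used everywhere downstream
METRICS = ("strength", "reaction_time", "relaxation_time", "magnitude_error", "direction_error")


class GripError(ValueError):
    """Raised for malformed trials or unsatisfiable preconditions."""


@dataclass(frozen=True)
class GripConfig:
    """Tunable parameters of the metric extraction.

    All times in seconds, forces in newtons, angles in degrees.
    """

    baseline_window_s: float = 0.5  # pre-cue window used for baseline mean/SD
    min_baseline_samples: int = 10
    threshold_sd: float = 3.0  # the 3-SD initiation/termination rule
    sd_floor_N: float = 1e-3  # avoids a zero-width threshold on noiseless traces
    sustain_s: float = 0.02  # threshold condition must hold this long
    max_latency_s: float = 5.0  # search horizon after the cue
    transient_s: float = 0.5  # excluded from the hold window after onset
    target_force_N: float = 4.0
    digit_combine: str = "mean"  # "mean" or "sum" of the two normal forces
    force_floor_N: float = 0.01  # minimum |F| for a defined force angle


@dataclass
class DigitForceTrial:
    """One grip trial: per-digit 3-axis force series plus cue times.

    ``forces[digit]`` is an (n_samples, 3) array of ``(Fn, Ft1, Ft2)`` where
    ``Fn`` is the component normal to the grip surface and ``Ft1``/``Ft2``
    span the tangential (shear) plane.
    """

    sampling_rate: float
    time: np.ndarray
    forces: dict[str, np.ndarray]
    cue_grip: float
    trial_kind: str
    hand: str
    cue_rest: float | None = None
    participant: str = ""
    repetition: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise GripError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.trial_kind not in TRIAL_KINDS:
            raise GripError(f"unknown trial_kind {self.trial_kind!r}")
        if self.hand not in HANDS:
            raise GripError(f"unknown hand {self.hand!r}")
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise GripError("time must be a 1-D array with at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise GripError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise GripError("time must be uniformly sampled")
        for digit, arr in self.forces.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.time.size, 3):
                raise GripError(
                    f"forces[{digit!r}] must have shape ({self.time.size}, 3), got {arr.shape}"
                )
            self.forces[digit] = arr
        span = (self.time[0], self.time[-1])
        if not span[0] <= self.cue_grip <= span[1]:
            raise GripError(f"cue_grip {self.cue_grip} outside recorded span {span}")
        if self.trial_kind == "target_grip":
            if self.cue_rest is None:
                raise GripError("target_grip trials require cue_rest")
            if not self.cue_grip < self.cue_rest:
                raise GripError("cue_grip must precede cue_rest")
            if not span[0] <= self.cue_rest <= span[1]:
                raise GripError(f"cue_rest {self.cue_rest} outside recorded span {span}")


@dataclass
class TrialMetrics:
    """Per-trial measures; ``None`` marks a metric that could not be determined."""

    strength: float | None = None
    reaction_time: float | None = None
    relaxation_time: float | None = None
    magnitude_error: float | None = None
    direction_error: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class HandSummary:
    """Per-hand repetition averages; a metric exists only with >= 1 valid rep."""

    hand: str
    means: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class PerformanceRatios:
    """The five paretic/(paretic+nonparetic) ratios for one participant."""

    participant: str
    ratios: dict[str, float | None] = field(default_factory=dict)


def grip_force_series(trial: DigitForceTrial, config: GripConfig | None = None) -> np.ndarray:
    """Scalar grip force: the two digits' normal components combined per sample."""
    config = config or GripConfig()
    for digit in DIGITS:
        if digit not in trial.forces:
            raise GripError(f"trial is missing forces for digit {digit!r}")
    stack = np.stack([trial.forces[d][:, 0] for d in DIGITS])
    if config.digit_combine == "mean":
        return stack.mean(axis=0)
    if config.digit_combine == "sum":
        return stack.sum(axis=0)
    raise GripError(f"unknown digit_combine {config.digit_combine!r}")


def baseline_stats(
    series: np.ndarray,
    time: np.ndarray,
    cue_grip: float,
    window_s: float,
    min_samples: int = 10,
) -> tuple[float, float]:
    """Sample mean and SD (ddof=1) over ``[cue_grip - window_s, cue_grip)``."""
    mask = (time >= cue_grip - window_s) & (time < cue_grip)
    n = int(mask.sum())
    if n < min_samples:
        raise GripError(
            f"baseline window [{cue_grip - window_s:.3f}, {cue_grip:.3f}) has only "
            f"{n} samples (need >= {min_samples})"
        )
    vals = np.asarray(series, dtype=float)[mask]
    return float(vals.mean()), float(vals.std(ddof=1))


def _first_sustained(cond: np.ndarray, start_idx: int, stop_idx: int, n_sustain: int) -> int | None:
    """First index in [start_idx, stop_idx] where ``cond`` holds for n_sustain
    consecutive samples (a run truncated by the end of the trace counts)."""
    n = cond.size
    c = np.concatenate(([0], np.cumsum(cond.astype(np.int64))))
    for i in range(start_idx, min(stop_idx, n - 1) + 1):
        m = min(n_sustain, n - i)
        if c[i + m] - c[i] == m:
            return i
    return None


def detect_onset(
    series: np.ndarray,
    time: np.ndarray,
    cue_grip: float,
    baseline_mean: float,
    baseline_sd: float,
    config: GripConfig | None = None,
) -> float | None:
    """Reaction time: first sustained crossing above baseline + 3 SD after the
    grip cue; ``None`` if no crossing occurs within the latency horizon."""
    config = config or GripConfig()
    time = np.asarray(time, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise GripError("time must be strictly increasing")
    thr = baseline_mean + config.threshold_sd * max(baseline_sd, config.sd_floor_N)
    cond = np.asarray(series, dtype=float) > thr
    fs = 1.0 / float(time[1] - time[0])
    start = int(np.searchsorted(time, cue_grip, side="left"))
    stop = int(np.searchsorted(time, cue_grip + config.max_latency_s, side="right")) - 1
    n_sustain = max(1, int(round(config.sustain_s * fs)))
    idx = _first_sustained(cond, start, stop, n_sustain)
    if idx is None:
        return None
    return float(time[idx] - cue_grip)


def detect_offset(
    series: np.ndarray,
    time: np.ndarray,
    cue_rest: float,
    baseline_mean: float,
    baseline_sd: float,
    config: GripConfig | None = None,
) -> float | None:
    """Relaxation time: first sustained return to within 3 SD of baseline after
    the rest cue; ``None`` if the force never returns in time."""
    config = config or GripConfig()
    time = np.asarray(time, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise GripError("time must be strictly increasing")
    thr = baseline_mean + config.threshold_sd * max(baseline_sd, config.sd_floor_N)
    cond = np.asarray(series, dtype=float) <= thr
    fs = 1.0 / float(time[1] - time[0])
    start = int(np.searchsorted(time, cue_rest, side="left"))
    stop = int(np.searchsorted(time, cue_rest + config.max_latency_s, side="right")) - 1
    n_sustain = max(1, int(round(config.sustain_s * fs)))
    idx = _first_sustained(cond, start, stop, n_sustain)
    if idx is None:
        return None
    return float(time[idx] - cue_rest)


def peak_strength(trial: DigitForceTrial, config: GripConfig | None = None) -> float:
    """Peak grip force over a maximum-grip trial (N)."""
    if trial.trial_kind != "max_grip":
        raise GripError(f"peak_strength requires a max_grip trial, got {trial.trial_kind!r}")
    series = grip_force_series(trial, config)
    if series.size == 0:
        raise GripError("empty force trace")
    return float(series.max())


def _hold_window_mask(trial: DigitForceTrial, onset_s: float, config: GripConfig) -> np.ndarray:
    t0 = trial.cue_grip + onset_s + config.transient_s
    return (trial.time >= t0) & (trial.time <= trial.cue_rest)


def magnitude_error(
    trial: DigitForceTrial, onset_s: float, config: GripConfig | None = None
) -> float | None:
    """|target - mean grip force| over the hold window (N); None if empty."""
    config = config or GripConfig()
    if trial.trial_kind != "target_grip":
        raise GripError("magnitude_error requires a target_grip trial")
    mask = _hold_window_mask(trial, onset_s, config)
    if not mask.any():
        return None
    series = grip_force_series(trial, config)
    return float(abs(config.target_force_N - series[mask].mean()))


def direction_error(
    trial: DigitForceTrial, onset_s: float, config: GripConfig | None = None
) -> float | None:
    """Mean angular deviation of digit force from the surface normal (degrees).

    Per digit and sample, theta = atan2(sqrt(Ft1^2 + Ft2^2), Fn); samples whose
    force magnitude is below the floor are skipped; digit means are averaged
    unweighted.  ``None`` when no digit has a defined angle in the window.
    """
    config = config or GripConfig()
    if trial.trial_kind != "target_grip":
        raise GripError("direction_error requires a target_grip trial")
    mask = _hold_window_mask(trial, onset_s, config)
    if not mask.any():
        return None
    digit_means = []
    for digit in DIGITS:
        if digit not in trial.forces:
            raise GripError(f"trial is missing forces for digit {digit!r}")
        f = trial.forces[digit][mask]
        mag = np.sqrt((f**2).sum(axis=1))
        ok = mag > config.force_floor_N
        if not ok.any():
            continue
        shear = np.sqrt(f[ok, 1] ** 2 + f[ok, 2] ** 2)
        theta = np.degrees(np.arctan2(shear, f[ok, 0]))
        digit_means.append(float(theta.mean()))
    if not digit_means:
        return None
    return float(np.mean(digit_means))


def compute_trial_metrics(trial: DigitForceTrial, config: GripConfig | None = None) -> TrialMetrics:
    """All metrics defined for one trial; undetectable ones are left ``None``."""
    config = config or GripConfig()
    out = TrialMetrics()
    if trial.trial_kind == "max_grip":
        out.strength = peak_strength(trial, config)
        return out
    series = grip_force_series(trial, config)
    mean, sd = baseline_stats(
        series, trial.time, trial.cue_grip, config.baseline_window_s, config.min_baseline_samples
    )
    onset = detect_onset(series, trial.time, trial.cue_grip, mean, sd, config)
    out.reaction_time = onset
    out.relaxation_time = detect_offset(series, trial.time, trial.cue_rest, mean, sd, config)
    if onset is not None:
        out.magnitude_error = magnitude_error(trial, onset, config)
        out.direction_error = direction_error(trial, onset, config)
    else:
        logger.warning(
            "participant %s %s trial %d: no grip onset detected; magnitude/direction skipped",
            trial.participant,
            trial.hand,
            trial.repetition,
        )
    return out


def summarize_hand(trials: list[TrialMetrics], hand: str) -> HandSummary:
    """Average valid repetitions per metric."""
    summary = HandSummary(hand=hand)
    for m in METRICS:
        vals = [tm.as_dict()[m] for tm in trials if tm.as_dict()[m] is not None]
        summary.counts[m] = len(vals)
        if vals:
            summary.means[m] = float(np.mean(vals))
    return summary


def compute_ratios(
    paretic: HandSummary, nonparetic: HandSummary, participant: str = ""
) -> PerformanceRatios:
    """ratio_m = paretic_m / (paretic_m + nonparetic_m) for each measure m."""
    ratios: dict[str, float | None] = {}
    for m in METRICS:
        p = paretic.means.get(m)
        n = nonparetic.means.get(m)
        if p is None or n is None:
            ratios[m] = None
            continue
        if p < 0 or n < 0:
            raise GripError(f"negative metric value for {m}: paretic={p}, nonparetic={n}")
        denom = p + n
        if denom == 0:
            logger.warning("participant %s: both hands zero for %s; ratio undefined", participant, m)
            ratios[m] = None
            continue
        ratios[m] = p / denom
    return PerformanceRatios(participant=participant, ratios=ratios)


def summarize_participant(
    trials: list[DigitForceTrial], participant: str = "", config: GripConfig | None = None
) -> tuple[HandSummary, HandSummary, PerformanceRatios]:
    """Trial metrics -> per-hand summaries -> performance ratios."""
    config = config or GripConfig()
    by_hand: dict[str, list[TrialMetrics]] = {h: [] for h in HANDS}
    for trial in trials:
        by_hand[trial.hand].append(compute_trial_metrics(trial, config))
    paretic = summarize_hand(by_hand["paretic"], "paretic")
    nonparetic = summarize_hand(by_hand["nonparetic"], "nonparetic")
    return paretic, nonparetic, compute_ratios(paretic, nonparetic, participant)
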