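"""Synthetic stroke-cohort generator with planted ground truth.

Every downstream stage is testable without clinical data: the generator
plants K latent network scores per participant and derives from them

* directed streamline-count matrices whose log-counts carry a two-level
  factor structure (in-network edges load on their network's score; counts
  are rounded log-normals, matching the heavy right skew of tractography
  streamline counts, and split into two directions with a small jitter so
  symmetrization is exercised);
* per-region lesion-volume fractions, optionally confounded with the scores
  (a lesioned network has both lower connectivity and worse performance);
* five grip-performance ratios linearly coupled to the scores through a
  5 x K standardized effect matrix; and
* raw digit-force trials (3 maximum grips + 3 target grips per hand at
  500 Hz, 4 N target) whose extracted metrics recover the planted per-hand
  values, closing the loop with the grip module.

Default cohort parameters mirror the study situation the pipeline is built
for: 22 participants, the 20-region sensorimotor set, three repetitions per
condition and hand, 2 s between grip and rest cue.  A single top-level seed
expands into fixed-offset child seeds so each component is independently
regenerable; everything is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.special import expit

from .connectome import edge_labels, split_edge
from .grip import METRICS, DigitForceTrial
from .regions import RegionInfo, default_distances, default_regions, volumes_series

logger = logging.getLogger(__name__)

# fixed child-seed offsets (one shared top-level seed expands into these)
_SEED_STRUCTURE = 0
_SEED_LATENTS = 1
_SEED_COUNTS = 2
_SEED_LESIONS = 3
_SEED_MEASURES = 4
_SEED_TRIALS = 5
_SEED_SIDES = 6

#: normative nonparetic-hand metric values (N, s, s, N, degrees)
NONPARETIC_NORMS = {
    "strength": 30.0,
    "reaction_time": 0.25,
    "relaxation_time": 0.30,
    "magnitude_error": 0.30,
    "direction_error": 8.0,
}


class SimulationError(ValueError):
    pass


def default_network_groups(region_names: list[str], n_networks: int) -> tuple[tuple[str, ...], ...]:
    """Split the region list into ``n_networks`` disjoint contiguous groups."""
    if not 1 <= n_networks <= len(region_names) // 2:
        raise SimulationError(f"n_networks must be in [1, {len(region_names) // 2}]")
    bounds = np.linspace(0, len(region_names), n_networks + 1).round().astype(int)
    return tuple(tuple(region_names[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))


def default_effects(n_networks: int) -> np.ndarray:
    """5 x K standardized effects: measure m driven by network m mod K.

    Signs follow the study's reporting direction: strength and magnitude load
    positively, the time and direction measures negatively.
    """
    signs = {"strength": 1.0, "reaction_time": -1.0, "relaxation_time": -1.0,
             "magnitude_error": 1.0, "direction_error": -1.0}
    e = np.zeros((len(METRICS), n_networks))
    for m, name in enumerate(METRICS):
        e[m, m % n_networks] = 0.5 * signs[name]
    return e


@dataclass
class CohortSpec:
    """Ground-truth data-generating configuration (all defaults = study scale)."""

    n_participants: int = 22
    n_networks: int = 3
    network_regions: tuple[tuple[str, ...], ...] | None = None  # default: contiguous split
    pattern_range: tuple[float, float] = (0.4, 0.9)  # in-network edge coefficients
    base_log_count: float = 5.0
    edge_base_sd: float = 0.5  # per-edge heterogeneity of the baseline log-count
    count_noise_sd: float = 0.3
    directed_jitter: float = 0.05  # relative split between the two directions
    effects: np.ndarray | None = None  # 5 x K; default: default_effects
    ratio_scale: float = 0.1  # SD of a ratio around 0.5 per unit latent
    ratio_clip: tuple[float, float] = (0.2, 0.8)
    lesion_intercept: float = -2.44  # logit of ~8 % mean lesion fraction
    lesion_scale: float = 1.0  # logit-units per unit lesion latent
    lesion_noise_sd: float = 0.5  # per-region logit noise
    lesion_score_coupling: float = 0.4  # b: corr(lesion latent, -score)
    lesion_performance_effect: float = 0.3  # c: direct lesion -> performance path
    sampling_rate: float = 500.0
    cue_grip_s: float = 1.0
    cue_rest_s: float = 3.0
    target_duration_s: float = 5.5
    max_duration_s: float = 3.0
    target_force_N: float = 4.0
    n_max_trials: int = 3
    n_target_trials: int = 3
    trial_noise_sd: float = 0.01  # force-sample noise, N
    rise_s: float = 0.15
    fall_s: float = 0.02
    hand_jitter_sd: float = 0.05  # lognormal jitter of nonparetic norms
    prob_left_lesion: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise SimulationError("need at least 2 participants")
        if not 0 <= abs(self.lesion_score_coupling) <= 1:
            raise SimulationError("lesion_score_coupling must be in [-1, 1]")
        for name in ("count_noise_sd", "lesion_noise_sd", "ratio_scale"):
            if not getattr(self, name) > 0:
                raise SimulationError(f"{name} must be positive")
        if self.effects is not None:
            self.effects = np.asarray(self.effects, dtype=float)
            if self.effects.shape != (len(METRICS), self.n_networks):
                raise SimulationError(
                    f"effects must be {len(METRICS)} x {self.n_networks}, got {self.effects.shape}"
                )
            if np.any(np.abs(self.effects) > 1):
                raise SimulationError("|effect| entries must be <= 1")

    # ---- derived, deterministic given the spec ----

    def regions(self) -> list[RegionInfo]:
        return default_regions()

    def region_names(self) -> list[str]:
        return [r.name for r in self.regions()]

    def groups(self) -> tuple[tuple[str, ...], ...]:
        if self.network_regions is not None:
            names = set(self.region_names())
            flat = [r for grp in self.network_regions for r in grp]
            if len(set(flat)) != len(flat):
                raise SimulationError("network region groups must be disjoint")
            unknown = [r for r in flat if r not in names]
            if unknown:
                raise SimulationError(f"unknown regions in network groups: {unknown}")
            if len(self.network_regions) != self.n_networks:
                raise SimulationError("network_regions must have n_networks groups")
            return self.network_regions
        return default_network_groups(self.region_names(), self.n_networks)

    def effect_matrix(self) -> np.ndarray:
        return self.effects if self.effects is not None else default_effects(self.n_networks)

    def participants(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_participants)]

    def network_names(self) -> list[str]:
        return [f"G{g + 1}" for g in range(self.n_networks)]


@dataclass
class GroundTruth:
    """Everything the generator planted, regenerable bit-exactly from (spec, seed)."""

    latent_scores: pd.DataFrame  # participants x networks
    pattern: pd.DataFrame  # edges x networks (planted composite edge weights)
    effects: pd.DataFrame  # measures x networks
    lesion_latents: pd.DataFrame  # participants x networks
    true_ratios: pd.DataFrame  # participants x measures
    paretic_true: pd.DataFrame  # participants x measures (pre-trial-noise)
    nonparetic_true: pd.DataFrame


@dataclass
class CohortData:
    """In-memory bundle of every input the analysis stages consume."""

    spec: CohortSpec
    participants: list[str]
    regions: list[RegionInfo]
    distances: pd.DataFrame
    raw_counts: dict[str, pd.DataFrame]  # canonical region names
    lesion_fractions: pd.DataFrame  # participants x regions
    lesion_sides: pd.Series  # participant -> "left"/"right"
    trials: dict[str, list[DigitForceTrial]] = field(default_factory=dict)
    truth: GroundTruth | None = None

    @property
    def volumes(self) -> pd.Series:
        return volumes_series(self.regions)


def sample_latents(spec: CohortSpec) -> pd.DataFrame:
    """Independent standard-normal network scores, participants x K."""
    rng = default_rng([spec.seed, _SEED_LATENTS])
    z = rng.standard_normal((spec.n_participants, spec.n_networks))
    return pd.DataFrame(z, index=spec.participants(), columns=spec.network_names())


def planted_pattern(spec: CohortSpec) -> pd.DataFrame:
    """Edges x networks coefficient matrix: U[pattern_range] on in-network edges."""
    rng = default_rng([spec.seed, _SEED_STRUCTURE])
    names = spec.region_names()
    edges = edge_labels(names)
    pattern = pd.DataFrame(0.0, index=edges, columns=spec.network_names())
    lo, hi = spec.pattern_range
    for g, grp in enumerate(spec.groups()):
        members = set(grp)
        for e in edges:
            a, b = split_edge(e)
            if a in members and b in members:
                pattern.iloc[pattern.index.get_loc(e), g] = rng.uniform(lo, hi)
    return pattern


def generate_counts(scores: pd.DataFrame, spec: CohortSpec) -> dict[str, pd.DataFrame]:
    """Directed streamline-count matrices (canonical region names) per participant."""
    rng = default_rng([spec.seed, _SEED_COUNTS])
    struct_rng = default_rng([spec.seed, _SEED_STRUCTURE, 1])
    names = spec.region_names()
    edges = edge_labels(names)
    pattern = planted_pattern(spec).to_numpy()
    base_e = struct_rng.normal(0.0, spec.edge_base_sd, size=len(edges))
    z = scores.to_numpy()
    logc = spec.base_log_count + base_e[None, :] + z @ pattern.T
    logc = logc + rng.normal(0.0, spec.count_noise_sd, size=logc.shape)
    sym = np.exp(logc)
    delta = rng.uniform(0.0, spec.directed_jitter, size=logc.shape)
    hi = np.maximum(np.round(sym * (1.0 + delta)), 0.0)
    lo = np.maximum(np.round(sym * (1.0 - delta)), 0.0)
    idx = {name: i for i, name in enumerate(names)}
    out: dict[str, pd.DataFrame] = {}
    for pi, participant in enumerate(scores.index):
        m = np.zeros((len(names), len(names)))
        for e, label in enumerate(edges):
            a, b = split_edge(label)
            m[idx[a], idx[b]] = hi[pi, e]
            m[idx[b], idx[a]] = lo[pi, e]
        out[str(participant)] = pd.DataFrame(m, index=names, columns=names)
    return out


def lesion_latents(scores: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Per-network standardized lesion latents: corr(latent, score) = -b."""
    rng = default_rng([spec.seed, _SEED_LESIONS])
    b = spec.lesion_score_coupling
    eta = rng.standard_normal(scores.shape)
    lat = -b * scores.to_numpy() + np.sqrt(max(1.0 - b**2, 0.0)) * eta
    return pd.DataFrame(lat, index=scores.index, columns=scores.columns)


def generate_lesions(
    scores: pd.DataFrame, spec: CohortSpec, latents: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-region lesion fractions in [0, 1], participants x regions."""
    rng = default_rng([spec.seed, _SEED_LESIONS, 1])
    if latents is None:
        latents = lesion_latents(scores, spec)
    names = spec.region_names()
    region_net = {}
    for g, grp in enumerate(spec.groups()):
        for r in grp:
            region_net[r] = spec.network_names()[g]
    out = np.empty((spec.n_participants, len(names)))
    for j, r in enumerate(names):
        noise = rng.normal(0.0, spec.lesion_noise_sd, size=spec.n_participants)
        drive = (
            spec.lesion_scale * latents[region_net[r]].to_numpy() if r in region_net else 0.0
        )
        out[:, j] = expit(spec.lesion_intercept + drive + noise)
    frac = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(frac, index=scores.index, columns=names)


def generate_measures(
    scores: pd.DataFrame, spec: CohortSpec, latents: pd.DataFrame | None = None
) -> GroundTruth:
    """True performance ratios and per-hand metric values (pre-trial-noise).

    The latent measure deviate is u_m = sum_g E[m,g] z_g
    + c * sum_{g in G_m} sign(E[m,g]) * (-lesion_latent_g) / sqrt(|G_m|)
    + sigma_m * eps, with sigma_m set so Var(u_m) = 1; the ratio is
    clip(0.5 + ratio_scale * u_m).  The paretic metric is then backed out of
    the ratio against a jittered normative nonparetic value, so extracting
    both hands' metrics reproduces the planted ratio.
    """
    rng = default_rng([spec.seed, _SEED_MEASURES])
    if latents is None:
        latents = lesion_latents(scores, spec)
    e = spec.effect_matrix()
    b = spec.lesion_score_coupling
    c = spec.lesion_performance_effect
    z = scores.to_numpy()
    lat = latents.to_numpy()
    n = spec.n_participants
    u = np.empty((n, len(METRICS)))
    for m in range(len(METRICS)):
        drive = z @ e[m]
        g_set = np.flatnonzero(e[m])
        var = float(e[m] @ e[m])
        if c > 0 and g_set.size:
            w = np.sign(e[m, g_set]) / np.sqrt(g_set.size)
            drive = drive + c * (-(lat[:, g_set] @ w))
            # Var(-c * w . lat) = c^2;   Cov(E z, -c w lat) = c*b*sum|E|/sqrt(|G|)
            var += c**2 + 2.0 * c * b * float(np.abs(e[m, g_set]).sum()) / np.sqrt(g_set.size)
        sigma = np.sqrt(max(1.0 - var, 0.04))
        if var > 1.0:
            logger.warning("measure %s: planted variance %.2f > 1; noise floored", METRICS[m], var)
        u[:, m] = drive + sigma * rng.standard_normal(n)
    lo, hi = spec.ratio_clip
    ratios = np.clip(0.5 + spec.ratio_scale * u, lo, hi)
    jitter = np.exp(rng.normal(0.0, spec.hand_jitter_sd, size=(n, len(METRICS))))
    nonp = np.array([NONPARETIC_NORMS[m] for m in METRICS])[None, :] * jitter
    paretic = nonp * ratios / (1.0 - ratios)
    participants = spec.participants()
    return GroundTruth(
        latent_scores=scores,
        pattern=planted_pattern(spec),
        effects=pd.DataFrame(e, index=list(METRICS), columns=spec.network_names()),
        lesion_latents=latents,
        true_ratios=pd.DataFrame(ratios, index=participants, columns=list(METRICS)),
        paretic_true=pd.DataFrame(paretic, index=participants, columns=list(METRICS)),
        nonparetic_true=pd.DataFrame(nonp, index=participants, columns=list(METRICS)),
    )


def _target_trial(
    spec: CohortSpec,
    rng,
    reaction: float,
    relaxation: float,
    hold_force: float,
    theta_deg: float,
    hand: str,
    participant: str,
    repetition: int,
) -> DigitForceTrial:
    fs = spec.sampling_rate
    dt = 1.0 / fs
    n = int(round(spec.target_duration_s * fs))
    t = np.arange(n) / fs
    # quantize initiation/termination to the sample grid and start the linear
    # rise one sample early, so the 3-SD threshold crossing is detected exactly
    # at the quantized instant (|detected - planted| <= half a sample)
    t_on = np.round((spec.cue_grip_s + reaction) * fs) / fs
    t_end = np.round((spec.cue_rest_s + relaxation) * fs) / fs
    t_rise_start = t_on - dt
    t_plateau = t_rise_start + spec.rise_s
    t_fall = t_end - spec.fall_s
    if not t_plateau < t_fall:
        raise SimulationError(
            f"infeasible trial timing: plateau {t_plateau:.3f} >= fall {t_fall:.3f}"
        )
    envelope = np.interp(
        t, [t_rise_start, t_plateau, t_fall, t_end], [0.0, hold_force, hold_force, 0.0]
    )
    envelope[t <= t_rise_start] = 0.0
    envelope[t >= t_end] = 0.0
    plateau = (t >= t_plateau) & (t <= t_fall)
    tan_theta = np.tan(np.radians(theta_deg))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    forces = {}
    for _digit in ("thumb", "index"):
        fn = envelope + (rng.normal(0.0, spec.trial_noise_sd, size=n) if spec.trial_noise_sd > 0 else 0.0)
        shear = np.where(plateau, fn * tan_theta, 0.0)
        forces[_digit] = np.column_stack([fn, shear * np.cos(phi), shear * np.sin(phi)])
    return DigitForceTrial(
        sampling_rate=fs,
        time=t,
        forces=forces,
        cue_grip=spec.cue_grip_s,
        cue_rest=spec.cue_rest_s,
        trial_kind="target_grip",
        hand=hand,
        participant=participant,
        repetition=repetition,
    )


def _max_trial(
    spec: CohortSpec, rng, strength: float, hand: str, participant: str, repetition: int
) -> DigitForceTrial:
    fs = spec.sampling_rate
    n = int(round(spec.max_duration_s * fs))
    t = np.arange(n) / fs
    cue = spec.cue_grip_s
    envelope = np.interp(t, [cue, cue + 0.8, cue + 1.6], [0.0, strength, 0.0])
    envelope[t < cue] = 0.0
    envelope[t > cue + 1.6] = 0.0
    forces = {}
    for _digit in ("thumb", "index"):
        fn = envelope + (rng.normal(0.0, spec.trial_noise_sd, size=n) if spec.trial_noise_sd > 0 else 0.0)
        forces[_digit] = np.column_stack([fn, np.zeros(n), np.zeros(n)])
    return DigitForceTrial(
        sampling_rate=fs,
        time=t,
        forces=forces,
        cue_grip=cue,
        cue_rest=None,
        trial_kind="max_grip",
        hand=hand,
        participant=participant,
        repetition=repetition,
    )


def generate_trials(truth: GroundTruth, spec: CohortSpec) -> dict[str, list[DigitForceTrial]]:
    """Raw force trials per participant whose extracted metrics recover the
    planted per-hand values (to within one sample / trace-noise)."""
    rng = default_rng([spec.seed, _SEED_TRIALS])
    out: dict[str, list[DigitForceTrial]] = {}
    for participant in truth.true_ratios.index:
        trials: list[DigitForceTrial] = []
        for hand, table in (("paretic", truth.paretic_true), ("nonparetic", truth.nonparetic_true)):
            row = table.loc[participant]
            for rep in range(spec.n_max_trials):
                trials.append(_max_trial(spec, rng, row["strength"], hand, participant, rep))
            for rep in range(spec.n_target_trials):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                hold = spec.target_force_N + sign * row["magnitude_error"]
                trials.append(
                    _target_trial(
                        spec,
                        rng,
                        reaction=row["reaction_time"],
                        relaxation=row["relaxation_time"],
                        hold_force=hold,
                        theta_deg=row["direction_error"],
                        hand=hand,
                        participant=participant,
                        repetition=rep,
                    )
                )
        out[participant] = trials
    return out


def generate_cohort(spec: CohortSpec, make_trials: bool = True) -> CohortData:
    """The full input bundle plus ground truth, deterministic in (spec, seed)."""
    sides_rng = default_rng([spec.seed, _SEED_SIDES])
    scores = sample_latents(spec)
    latents = lesion_latents(scores, spec)
    counts = generate_counts(scores, spec)
    lesions = generate_lesions(scores, spec, latents)
    truth = generate_measures(scores, spec, latents)
    trials = generate_trials(truth, spec) if make_trials else {}
    sides = pd.Series(
        np.where(sides_rng.random(spec.n_participants) < spec.prob_left_lesion, "left", "right"),
        index=spec.participants(),
        name="lesion_side",
    )
    regions = spec.regions()
    return CohortData(
        spec=spec,
        participants=spec.participants(),
        regions=regions,
        distances=default_distances(regions),
        raw_counts=counts,
        lesion_fractions=lesions,
        lesion_sides=sides,
        trials=trials,
        truth=truth,
    )
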