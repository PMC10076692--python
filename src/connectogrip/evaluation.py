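"""Parameter-recovery and calibration experiments on planted-truth cohorts.

These routines quantify, on synthetic cohorts with known ground truth, how
faithfully the pipeline recovers what was planted: metric round-trip error,
factor-model numerical accuracy against closed-form oracles, two-level
network recovery, association-effect calibration and type-I error, the
benefit of the lesion covariate under confounding, and bit-level
determinism.  They are used by the test suite and by scripts/acceptance.py.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig
from .factor import FactorConfig, fit_factor_model, match_factors, standardize_columns
from .grip import METRICS, compute_trial_metrics
from .pipeline import run_pipeline
from .simulate import CohortSpec, generate_cohort

_HAND_TRUTH = {"paretic": "paretic_true", "nonparetic": "nonparetic_true"}


def _child_seed(seed: int, i: int) -> int:
    return (seed * 1009 + i) % (2**31 - 1)


# ------------------------------------------------------------ metric round trip

def metric_roundtrip_errors(seed: int = 0, n_participants: int = 17) -> dict[str, float]:
    """Max |extracted - planted| over all noiseless trials (>= 200 by default:
    17 participants x 12 trials)."""
    spec = CohortSpec(n_participants=n_participants, trial_noise_sd=0.0, seed=_child_seed(seed, 1))
    cohort = generate_cohort(spec, make_trials=True)
    errs: dict[str, list[float]] = {m: [] for m in METRICS}
    n_trials = 0
    for participant in cohort.participants:
        for trial in cohort.trials[participant]:
            n_trials += 1
            truth = getattr(cohort.truth, _HAND_TRUTH[trial.hand]).loc[participant]
            metrics = compute_trial_metrics(trial)
            for m, v in metrics.as_dict().items():
                if v is not None:
                    errs[m].append(abs(v - truth[m]))
    assert n_trials >= 200
    return {
        "n_trials": float(n_trials),
        "reaction_time_s": max(errs["reaction_time"]),
        "relaxation_time_s": max(errs["relaxation_time"]),
        "magnitude_error_N": max(errs["magnitude_error"]),
        "direction_error_deg": max(errs["direction_error"]),
        "strength_N": max(errs["strength"]),
    }


# ------------------------------------------------------------ factor oracles

def factor_oracle_deviations(seed: int = 0) -> dict[str, float]:
    """Numerical deviation of the factor machinery from independent oracles."""
    rng = np.random.default_rng(_child_seed(seed, 2))

    # principal-component loadings vs an SVD of the standardized data
    x = pd.DataFrame(rng.normal(size=(150, 8)) @ rng.normal(size=(8, 8)))
    x.columns = [f"v{j}" for j in range(8)]
    model = fit_factor_model(x, FactorConfig(retention="fixed_k", fixed_k=3, rotation="none"))
    z, _ = standardize_columns(x)
    _, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    oracle = vt.T[:, :3] * (s[:3] / np.sqrt(len(x) - 1))
    for j in range(3):
        if oracle[np.argmax(np.abs(oracle[:, j])), j] < 0:
            oracle[:, j] *= -1
    pc_dev = float(np.max(np.abs(model.loadings.to_numpy() - oracle)))

    # varimax preserves communalities
    rot = fit_factor_model(x, FactorConfig(retention="fixed_k", fixed_k=3, rotation="varimax"))
    comm_dev = float(
        np.max(np.abs(rot.communalities.to_numpy() - model.communalities.to_numpy()))
    )

    # regression scores vs the closed form Z R^-1 Lambda on an exact hand-built
    # 5-variable correlation matrix
    r_target = np.array(
        [
            [1.0, 0.5, 0.3, 0.1, 0.0],
            [0.5, 1.0, 0.4, 0.2, 0.1],
            [0.3, 0.4, 1.0, 0.3, 0.2],
            [0.1, 0.2, 0.3, 1.0, 0.4],
            [0.0, 0.1, 0.2, 0.4, 1.0],
        ]
    )
    raw = rng.normal(size=(80, 5))
    centered = raw - raw.mean(0)
    white = centered @ np.linalg.inv(np.linalg.cholesky(np.cov(centered, rowvar=False))).T
    y = pd.DataFrame(white @ np.linalg.cholesky(r_target).T, columns=list("abcde"))
    m2 = fit_factor_model(y, FactorConfig(retention="fixed_k", fixed_k=2, rotation="varimax"))
    zy, _ = standardize_columns(y)
    raw_scores = zy.to_numpy() @ np.linalg.inv(r_target) @ m2.loadings.to_numpy()
    oracle_scores = raw_scores / raw_scores.std(0, ddof=1)
    score_dev = float(np.max(np.abs(m2.scores.to_numpy() - oracle_scores)))

    return {
        "pc_loading_dev": pc_dev,
        "varimax_communality_dev": comm_dev,
        "regression_score_dev": score_dev,
    }


# ------------------------------------------------------------ two-level recovery

def _recovered_weights(result) -> np.ndarray:
    return np.column_stack(
        [result.networks[n].weights.to_numpy() for n in result.second.network_names]
    )


def two_level_recovery(seed: int = 0, n_seeds: int = 20, n: int = 300) -> dict[str, float]:
    """Planted K=3 disjoint networks, in-network weights in [0.6, 0.9],
    count-noise SD 0.3: how often is K recovered exactly, and how congruent
    are the composite edge-weight vectors with the planted patterns."""
    exact = 0
    congruences = []
    for i in range(n_seeds):
        s = _child_seed(seed, 100 + i)
        spec = CohortSpec(n_participants=n, n_networks=3, pattern_range=(0.6, 0.9),
                          count_noise_sd=0.3, seed=s)
        cohort = generate_cohort(spec, make_trials=False)
        result = run_pipeline(cohort, RunConfig(seed=s))
        exact += int(len(result.second.network_names) == 3)
        _, congr = match_factors(_recovered_weights(result), cohort.truth.pattern.to_numpy())
        congruences.append(congr.mean())
    return {
        "n_seeds": float(n_seeds),
        "exact_k_fraction": exact / n_seeds,
        "mean_congruence": float(np.mean(congruences)),
    }


# ------------------------------------------------------------ association calibration

def _matched_cell(result, cohort, planted_net: int, measure: str) -> pd.Series:
    assignment, _ = match_factors(_recovered_weights(result), cohort.truth.pattern.to_numpy())
    net = result.second.network_names[assignment[planted_net]]
    cells = result.association.cells
    return cells[(cells.network == net) & (cells.measure == measure)].iloc[0]


def association_calibration(seed: int = 0, n_reps: int = 500, n: int = 100) -> dict[str, float]:
    """Planted standardized effect 0.5 on one (measure, network) pair, no
    lesion confounding: the mean estimated lesion-adjusted partial r."""
    effects = np.zeros((5, 3))
    effects[0, 0] = 0.5
    vals = []
    for i in range(n_reps):
        s = _child_seed(seed, 1000 + i)
        spec = CohortSpec(n_participants=n, n_networks=3, effects=effects,
                          lesion_score_coupling=0.0, lesion_performance_effect=0.0, seed=s)
        cohort = generate_cohort(spec, make_trials=False)
        result = run_pipeline(cohort, RunConfig(seed=s))
        vals.append(abs(_matched_cell(result, cohort, 0, "strength").partial_r))
    return {"n_reps": float(n_reps), "mean_partial_r": float(np.mean(vals))}


def null_type_i(seed: int = 0, n_reps: int = 1000, n: int = 50) -> dict[str, float]:
    """All effects zero: rejection rate of the nominal 5% two-sided test on the
    network beta in one fixed grid cell."""
    effects = np.zeros((5, 3))
    rejections = 0
    for i in range(n_reps):
        s = _child_seed(seed, 20_000 + i)
        spec = CohortSpec(n_participants=n, n_networks=3, effects=effects,
                          lesion_score_coupling=0.0, lesion_performance_effect=0.0, seed=s)
        cohort = generate_cohort(spec, make_trials=False)
        result = run_pipeline(cohort, RunConfig(seed=s))
        cells = result.association.cells
        row = cells[
            (cells.network == result.second.network_names[0]) & (cells.measure == "strength")
        ].iloc[0]
        rejections += int(row.p_value < 0.05)
    return {"n_reps": float(n_reps), "rejection_rate": rejections / n_reps}


def confounding_control(seed: int = 0, n_runs: int = 100, n: int = 100) -> dict[str, float]:
    """Lesion coupling strong enough that the simple correlation overstates the
    planted effect 0.5: is the lesion-adjusted partial r closer to truth."""
    effects = np.zeros((5, 3))
    effects[0, 0] = 0.5
    partials, simples = [], []
    for i in range(n_runs):
        s = _child_seed(seed, 40_000 + i)
        spec = CohortSpec(n_participants=n, n_networks=3, effects=effects,
                          lesion_score_coupling=0.6, lesion_performance_effect=0.5, seed=s)
        cohort = generate_cohort(spec, make_trials=False)
        result = run_pipeline(cohort, RunConfig(seed=s))
        cell = _matched_cell(result, cohort, 0, "strength")
        partials.append(abs(cell.partial_r))
        simples.append(abs(cell.simple_r))
    partials, simples = np.asarray(partials), np.asarray(simples)
    closer = np.abs(partials - 0.5) < np.abs(simples - 0.5)
    return {
        "n_runs": float(n_runs),
        "mean_partial_r": float(partials.mean()),
        "mean_simple_r": float(simples.mean()),
        "simple_overstatement": float(simples.mean() - 0.5),
        "partial_closer_fraction": float(closer.mean()),
    }


# ------------------------------------------------------------ end-to-end

def end_to_end_accuracy(seed: int = 0, n_seeds: int = 50, n: int = 150) -> dict[str, float]:
    """Five measures driven by five distinct planted networks (effect 0.6):
    fraction of full pipeline runs (raw trials included) where the
    best-network flag matches the planted pairing for all five measures,
    with and without the lesion covariate."""
    signs = np.array([1.0, -1.0, -1.0, 1.0, -1.0])
    effects = 0.6 * np.eye(5) * signs[:, None]
    ok_adj = ok_unadj = 0
    for i in range(n_seeds):
        s = _child_seed(seed, 60_000 + i)
        spec = CohortSpec(n_participants=n, n_networks=5, effects=effects, seed=s)
        cohort = generate_cohort(spec, make_trials=True)
        result = run_pipeline(cohort, RunConfig(seed=s))
        assignment, _ = match_factors(_recovered_weights(result), cohort.truth.pattern.to_numpy())
        names = result.second.network_names
        ok_adj += int(
            all(result.association.best_network[m] == names[assignment[g]]
                for g, m in enumerate(METRICS))
        )
        ok_unadj += int(
            all(result.association.best_network_uncontrolled[m] == names[assignment[g]]
                for g, m in enumerate(METRICS))
        )
    return {
        "n_seeds": float(n_seeds),
        "adjusted_accuracy": ok_adj / n_seeds,
        "unadjusted_accuracy": ok_unadj / n_seeds,
    }


# ------------------------------------------------------------ determinism

def determinism_check(out_dir, seed: int = 0) -> dict[str, float]:
    """Identical (inputs, config, seed) must reproduce byte-identical outputs,
    and every writer must round-trip value-identically."""
    out_dir = Path(out_dir)
    spec = CohortSpec(n_participants=12, seed=_child_seed(seed, 3))
    blobs = []
    for run in ("a", "b"):
        d = out_dir / run
        d.mkdir(parents=True, exist_ok=True)
        cohort = generate_cohort(spec, make_trials=True)
        io.write_cohort(cohort, d / "cohort")
        loaded = io.read_cohort(d / "cohort")
        result = run_pipeline(loaded, RunConfig(seed=spec.seed))
        io.write_association_csv(result.association.cells, d / "association.csv")
        io.write_scores_csv(result.second.scores, d / "scores.csv")
        blobs.append(
            (d / "association.csv").read_bytes()
            + (d / "scores.csv").read_bytes()
            + (d / "cohort" / "ground_truth.json").read_bytes()
        )
    identical = blobs[0] == blobs[1]

    # writer round trip on the last cohort
    cohort = generate_cohort(spec, make_trials=False)
    d = out_dir / "rt"
    io.write_cohort(cohort, d)
    back = io.read_cohort(d)
    round_trip = all(
        back.raw_counts[p].equals(cohort.raw_counts[p]) for p in cohort.participants
    ) and back.lesion_fractions.equals(cohort.lesion_fractions)
    return {"byte_identical": float(identical), "round_trip_identical": float(round_trip)}
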