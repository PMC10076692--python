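"""Two-level exploratory factor analysis of connectome edge weights.

Level 1 fits, separately for each region *i*, a factor model of the 19 edge
weights between *i* and the other regions across participants.  Level 2
pools all retained first-level factor scores and fits a second factor model
whose factors are the latent *networks*; per-participant network scores are
the independent variables of the downstream regressions.

Extraction is principal-component (eigendecomposition of the sample
correlation matrix; no invertibility assumed, so the n < p regime of small
clinical cohorts is handled), with iterated principal-axis available.
Retention defaults to Horn's parallel analysis: a factor is kept while its
eigenvalue exceeds the 95th permutation percentile of the matching
eigenvalue under independently column-shuffled data.  The classical Kaiser
eigenvalue-greater-than-1 rule is available but retains many
sampling-noise factors whenever p/n is non-negligible (the bulk of the
Marchenko-Pastur spectrum sits above 1), which cascades into a spuriously
large number of second-level "networks"; see docs/methods.md.  Rotation is
varimax (orthogonal, communality-preserving), scores use the regression
(Thurstone) method with a pseudoinverse when the correlation matrix is
singular, and a deterministic sign convention (largest-|loading| positive)
plus descending explained-variance ordering make runs bit-reproducible.

For reporting, each network is summarized by composite edge weights: for
edge e and network g the candidate contributions are
loading(e -> first-level factor p) * loading(p -> g) over every first-level
factor p of the two regions incident to e; the candidate of largest absolute
value (sign kept) is the composite weight.  Edges with |weight| >= 0.4 are
reported, at most the top 6 per network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.optimize import linear_sum_assignment

from .connectome import edge_labels, region_edge_view, split_edge

logger = logging.getLogger(__name__)

EXTRACTIONS = ("principal_component", "principal_axis")
RETENTIONS = ("parallel_analysis", "kaiser_eigenvalue_gt_1", "fixed_k")
ROTATIONS = ("varimax", "none")
COMBINES = ("max_abs", "sum")


class FactorError(ValueError):
    """Raised for unusable inputs or an empty retention set."""


class NoFactorsRetainedError(FactorError):
    """No factor met the retention rule; consider retention='fixed_k'."""


EDGE_TRANSFORMS = ("log1p", "none")


@dataclass(frozen=True)
class FactorConfig:
    extraction: str = "principal_component"
    retention: str = "parallel_analysis"
    fixed_k: int | None = None
    rotation: str = "varimax"
    score_method: str = "regression"
    zscore_inputs: bool = True
    # variance-stabilizing transform of the edge weights before correlation;
    # streamline-count-derived weights are heavily right-skewed and Pearson
    # correlations of raw log-normal variables are attenuated
    edge_transform: str = "log1p"
    pa_permutations: int = 30
    # 99th percentile rather than Horn's conventional 95th: retention is run
    # once per region (20 tests per cohort), so the per-test false-positive
    # rate must be small for the cohort-wise rate to stay controlled
    pa_quantile: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_transform not in EDGE_TRANSFORMS:
            raise FactorError(f"unknown edge_transform {self.edge_transform!r}")
        if self.extraction not in EXTRACTIONS:
            raise FactorError(f"unknown extraction {self.extraction!r}")
        if self.retention not in RETENTIONS:
            raise FactorError(f"unknown retention {self.retention!r}")
        if self.retention == "fixed_k" and (self.fixed_k is None or self.fixed_k < 1):
            raise FactorError("retention='fixed_k' requires fixed_k >= 1")
        if self.rotation not in ROTATIONS:
            raise FactorError(f"unknown rotation {self.rotation!r}")
        if self.score_method != "regression":
            raise FactorError(f"unknown score_method {self.score_method!r}")


@dataclass
class FactorModel:
    """One fitted factor model (either level)."""

    loadings: pd.DataFrame  # variables x factors
    scores: pd.DataFrame  # participants x factors, column-standardized
    eigenvalues: np.ndarray  # full spectrum of the correlation matrix
    communalities: pd.Series
    score_weights: pd.DataFrame  # variables x factors: scores = Z @ W, then standardized
    score_scale: np.ndarray  # per-factor SD divided out during standardization
    dropped_columns: list[str] = field(default_factory=list)
    config: FactorConfig | None = None

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


@dataclass
class SecondLevelModel:
    """Pooled-score factor model whose factors are the latent networks."""

    model: FactorModel
    first_level: dict[str, FactorModel]

    @property
    def network_names(self) -> list[str]:
        return list(self.model.loadings.columns)

    @property
    def scores(self) -> pd.DataFrame:
        return self.model.scores


@dataclass
class NetworkDefinition:
    """Composite edge weights of one network plus the reported top edges."""

    network: str
    weights: pd.Series  # signed composite weight per undirected edge
    reported: pd.DataFrame  # edge, region_a, region_b, weight (|w| >= threshold, top n)
    threshold: float
    top_n: int


def standardize_columns(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column z-scores (ddof=1); zero-variance columns are dropped with a warning."""
    if table.shape[0] < 2:
        raise FactorError(f"need >= 2 rows to standardize, got {table.shape[0]}")
    vals = table.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise FactorError("table contains non-finite values")
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 1e-12
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped[:8])
    z = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]
    return pd.DataFrame(z, index=table.index, columns=table.columns[keep]), dropped


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Varimax with Kaiser row normalization; returns the k x k rotation."""
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    h = np.sqrt((loadings**2).sum(axis=1))
    h[h == 0] = 1.0
    a = loadings / h[:, None]
    rot = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        b = a @ rot
        grad = a.T @ (b**3 - b @ np.diag((b**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        rot = u @ vt
        new = s.sum()
        if new <= obj * (1 + tol):
            break
        obj = new
    return rot


def _pa_thresholds(z: np.ndarray, config: FactorConfig, rng) -> np.ndarray:
    """Per-rank eigenvalue thresholds from independently column-shuffled data.

    Columns are sorted before shuffling so the draw depends only on each
    column's value multiset: permuting participant rows cannot change the
    thresholds (and hence the retention decision).
    """
    n, p = z.shape
    eigs = np.empty((config.pa_permutations, p))
    zp = np.sort(z, axis=0)
    for b in range(config.pa_permutations):
        for j in range(p):
            rng.shuffle(zp[:, j])
        r = (zp.T @ zp) / (n - 1)
        eigs[b] = np.linalg.eigvalsh(r)[::-1]
    return np.quantile(eigs, config.pa_quantile, axis=0)


def _retain(eigenvalues: np.ndarray, z: np.ndarray, config: FactorConfig, rng) -> int:
    if config.retention == "fixed_k":
        return min(int(config.fixed_k), z.shape[1])
    if config.retention == "kaiser_eigenvalue_gt_1":
        # strict "greater than 1" with a numerical guard so an exactly-unit
        # eigenvalue (e.g. a single variable) does not count
        return int((eigenvalues > 1.0 + 1e-10).sum())
    thresholds = _pa_thresholds(z, config, rng)
    k = 0
    for lam, thr in zip(eigenvalues, thresholds):
        if lam > thr:
            k += 1
        else:
            break
    return k


def _principal_axis_loadings(r: np.ndarray, k: int, max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring: re-estimate communalities on the diagonal."""
    p = r.shape[0]
    rinv_diag = np.diag(np.linalg.pinv(r))
    with np.errstate(divide="ignore"):
        comm = np.where(rinv_diag > 0, 1.0 - 1.0 / rinv_diag, 0.5)
    comm = np.clip(comm, 0.0, 1.0)
    for _ in range(max_iter):
        rh = r.copy()
        np.fill_diagonal(rh, comm)
        evals, evecs = np.linalg.eigh(rh)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        lam = np.sqrt(np.clip(evals[:k], 0, None))
        load = evecs[:, :k] * lam
        new_comm = np.clip((load**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            break
        comm = new_comm
    rh = r.copy()
    np.fill_diagonal(rh, comm)
    evals, evecs = np.linalg.eigh(rh)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    return evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))


def fit_factor_model(
    table: pd.DataFrame,
    config: FactorConfig | None = None,
    factor_prefix: str = "F",
    rng=None,
) -> FactorModel:
    """Fit one factor model on a participants x variables table."""
    config = config or FactorConfig()
    if rng is None:
        rng = default_rng(config.seed)
    if config.zscore_inputs:
        ztab, dropped = standardize_columns(table)
    else:
        ztab, dropped = table.copy(), []
    z = ztab.to_numpy(dtype=float)
    n, p = z.shape
    if p < 1:
        raise FactorError("no usable variables after dropping zero-variance columns")
    r = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(r)
    evals, evecs = evals[::-1].copy(), evecs[:, ::-1].copy()
    evals = np.clip(evals, 0.0, None)
    k = _retain(evals, z, config, rng)
    if k < 1:
        raise NoFactorsRetainedError(
            f"retention rule {config.retention!r} kept no factors "
            f"(top eigenvalue {evals[0]:.3f}); consider retention='fixed_k'"
        )
    if config.extraction == "principal_component":
        loadings = evecs[:, :k] * np.sqrt(evals[:k])
    else:
        loadings = _principal_axis_loadings(r, k)
    if config.rotation == "varimax" and k > 1:
        rot = _varimax(loadings)
        loadings = loadings @ rot
    # deterministic ordering: descending explained variance (sum of squared loadings)
    order = np.argsort(-(loadings**2).sum(axis=0), kind="stable")
    loadings = loadings[:, order]
    # deterministic sign: the largest-|loading| entry of each factor is positive
    for j in range(k):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] = -loadings[:, j]
    # regression (Thurstone) scores; pseudoinverse handles the singular n < p case
    w = np.linalg.pinv(r) @ loadings
    raw_scores = z @ w
    scale = raw_scores.std(axis=0, ddof=1)
    if np.any(scale <= 1e-12):
        raise FactorError("degenerate factor scores (zero variance)")
    scores = raw_scores / scale
    names = [f"{factor_prefix}{j + 1}" for j in range(k)]
    return FactorModel(
        loadings=pd.DataFrame(loadings, index=ztab.columns, columns=names),
        scores=pd.DataFrame(scores, index=ztab.index, columns=names),
        eigenvalues=evals,
        communalities=pd.Series((loadings**2).sum(axis=1), index=ztab.columns),
        score_weights=pd.DataFrame(w, index=ztab.columns, columns=names),
        score_scale=scale,
        dropped_columns=dropped,
        config=config,
    )


FIRST_LEVEL_SEP = "::"


def first_level(
    edge_table: pd.DataFrame,
    regions: list[str],
    config: FactorConfig | None = None,
) -> dict[str, FactorModel]:
    """One factor model per region over its incident-edge view.

    Regions where the retention rule keeps nothing contribute no factors (a
    warning is logged); an error is raised only if *every* region is empty.
    """
    config = config or FactorConfig()
    if edge_table.shape[0] < 3:
        raise FactorError(f"need >= 3 participants, got {edge_table.shape[0]}")
    if config.edge_transform == "log1p":
        if (edge_table.to_numpy() < 0).any():
            raise FactorError("edge weights must be nonnegative for the log1p transform")
        edge_table = np.log1p(edge_table)
    models: dict[str, FactorModel] = {}
    for idx, region in enumerate(regions):
        view = region_edge_view(edge_table, regions, region)
        rng = default_rng([config.seed, idx])
        try:
            model = fit_factor_model(view, config, factor_prefix="F", rng=rng)
        except NoFactorsRetainedError:
            logger.warning("region %s: no first-level factor retained", region)
            continue
        except FactorError as exc:
            raise FactorError(f"region {region}: {exc}") from exc
        model.loadings.columns = [f"{region}{FIRST_LEVEL_SEP}{c}" for c in model.loadings.columns]
        model.scores.columns = model.loadings.columns
        model.score_weights.columns = model.loadings.columns
        models[region] = model
    if not models:
        raise NoFactorsRetainedError("no region retained any first-level factor")
    return models


def second_level(
    first: dict[str, FactorModel],
    config: FactorConfig | None = None,
) -> SecondLevelModel:
    """Factor the pooled first-level scores into latent networks."""
    config = config or FactorConfig()
    pooled = pd.concat([m.scores for m in first.values()], axis=1)
    if pooled.isna().any().any():
        raise FactorError("first-level scores are misaligned across regions")
    if pooled.shape[1] < 2:
        raise FactorError(
            f"pooled first-level score table has {pooled.shape[1]} column(s); need >= 2"
        )
    rng = default_rng([config.seed, 10_000])
    model = fit_factor_model(pooled, config, factor_prefix="N", rng=rng)
    return SecondLevelModel(model=model, first_level=first)


def composite_edge_weights(
    second: SecondLevelModel,
    network: str,
    regions: list[str],
    threshold: float = 0.4,
    top_n: int = 6,
    combine: str = "max_abs",
) -> NetworkDefinition:
    """Edge-level composite weights of one network (see module docstring)."""
    if network not in second.network_names:
        raise FactorError(f"unknown network {network!r}; have {second.network_names}")
    if combine not in COMBINES:
        raise FactorError(f"unknown combine rule {combine!r}")
    l2 = second.model.loadings[network]
    weights = pd.Series(0.0, index=edge_labels(regions), name=network)
    for edge in weights.index:
        a, b = split_edge(edge)
        candidates: list[float] = []
        for region in (a, b):
            model = second.first_level.get(region)
            if model is None or edge not in model.loadings.index:
                continue
            for factor in model.loadings.columns:
                candidates.append(float(model.loadings.at[edge, factor] * l2[factor]))
        if not candidates:
            continue
        if combine == "max_abs":
            weights[edge] = max(candidates, key=abs)
        else:
            weights[edge] = float(np.sum(candidates))
    eligible = weights[weights.abs() >= threshold]
    # ties broken by edge label order: stable sort on -|w| after sorting labels
    eligible = eligible.loc[sorted(eligible.index)]
    top = eligible.iloc[np.argsort(-eligible.abs().to_numpy(), kind="stable")[:top_n]]
    reported = pd.DataFrame(
        {
            "edge": top.index,
            "region_a": [split_edge(e)[0] for e in top.index],
            "region_b": [split_edge(e)[1] for e in top.index],
            "weight": top.to_numpy(),
        }
    ).reset_index(drop=True)
    return NetworkDefinition(
        network=network, weights=weights, reported=reported, threshold=threshold, top_n=top_n
    )


def network_scores(second: SecondLevelModel, participant: str) -> pd.Series:
    """One participant's standardized network scores."""
    if participant not in second.scores.index:
        raise FactorError(f"participant {participant!r} not in the fitted cohort")
    return second.scores.loc[participant]


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine-type similarity between two loading/weight vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_factors(recovered: np.ndarray, planted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match columns of ``recovered`` to columns of ``planted`` by maximal
    |Tucker congruence| (Hungarian assignment).

    Returns ``(assignment, congruences)`` where ``assignment[j]`` is the
    recovered column matched to planted column j and ``congruences[j]`` the
    |congruence| of that pair.
    """
    kp = planted.shape[1]
    kr = recovered.shape[1]
    phi = np.zeros((kp, kr))
    for i in range(kp):
        for j in range(kr):
            phi[i, j] = abs(tucker_congruence(planted[:, i], recovered[:, j]))
    rows, cols = linear_sum_assignment(-phi)
    assignment = np.full(kp, -1, dtype=int)
    congr = np.zeros(kp)
    for i, j in zip(rows, cols):
        assignment[i] = j
        congr[i] = phi[i, j]
    return assignment, congr
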