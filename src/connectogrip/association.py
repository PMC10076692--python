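"""Lesion-adjusted network-performance associations.

For every (network, grip measure) pair an ordinary least-squares model is
fitted on standardized variables:

    measure_ratio ~ network_score + network_lesion_percent

The reported quantities per cell are the partial correlation of measure and
score given lesion load, the standardized slope (beta) with its SE (because
all variables are z-scored, beta is on the correlation scale), the plain
(uncontrolled) correlation, and the variance inflation factors of the two
predictors.  Per measure, the network with the largest |partial r| is
flagged as the best-explaining network; the same call is repeated on the
uncontrolled grid to check whether findings are consistent with and without
the lesion covariate.

The lesion covariate of a network is the volume-weighted percent of lesioned
tissue over the network's regions, with continuous node memberships: region
r's membership in network g is the largest |composite edge weight| over the
edges incident to r (unthresholded, so every network has a nonzero
denominator).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectome import split_edge
from .factor import NetworkDefinition
from .grip import METRICS

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    """Raised for misaligned inputs or degenerate designs."""


@dataclass
class RegressionResult:
    """One (network, measure) cell of the association grid."""

    network: str
    measure: str
    partial_r: float
    beta: float
    se: float
    p_value: float
    simple_r: float
    vif_score: float
    vif_lesion: float
    n: int


@dataclass
class AssociationTable:
    """Networks x measures grid plus per-measure best-network flags."""

    cells: pd.DataFrame  # long form, one row per (network, measure)
    best_network: dict[str, str]  # measure -> flagged network (max |partial_r|)
    best_network_uncontrolled: dict[str, str]  # measure -> flag by |simple_r|
    consistent_with_unadjusted: bool

    def grid(self, value: str = "partial_r") -> pd.DataFrame:
        return self.cells.pivot(index="network", columns="measure", values=value)


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 1e-12:
        raise AssociationError(f"predictor/outcome {name!r} is constant")
    return (x - x.mean()) / sd


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Pearson correlation of x and y after removing the linear effect of z."""
    rxy = float(np.corrcoef(x, y)[0, 1])
    rxz = float(np.corrcoef(x, z)[0, 1])
    ryz = float(np.corrcoef(y, z)[0, 1])
    denom = math.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom <= 1e-15:
        raise AssociationError("covariate is perfectly collinear with x or y")
    return (rxy - rxz * ryz) / denom


def vif(design: pd.DataFrame, warn_threshold: float = 10.0) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2 of k on the rest).

    Perfect collinearity yields ``inf`` with a warning, never an exception.
    """
    if design.shape[1] < 2:
        raise AssociationError("VIF needs at least two predictors")
    out = {}
    x = design.to_numpy(dtype=float)
    for j, name in enumerate(design.columns):
        others = np.column_stack([np.ones(len(x)), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ coef
        tss = float(((x[:, j] - x[:, j].mean()) ** 2).sum())
        if tss <= 1e-15:
            raise AssociationError(f"predictor {name!r} is constant")
        r2 = 1.0 - float((resid**2).sum()) / tss
        if r2 >= 1.0 - 1e-12:
            logger.warning("predictor %r is perfectly collinear; VIF = inf", name)
            out[name] = math.inf
            continue
        v = 1.0 / (1.0 - r2)
        if v > warn_threshold:
            logger.warning("predictor %r has VIF %.1f above threshold %.1f", name, v, warn_threshold)
        out[name] = v
    return pd.Series(out)


def fit_association(
    measure: np.ndarray,
    score: np.ndarray,
    lesion: np.ndarray,
    network: str = "",
    measure_name: str = "",
    vif_warn: float = 10.0,
) -> RegressionResult:
    """OLS of a measure on one network score plus its lesion covariate."""
    measure = np.asarray(measure, dtype=float)
    score = np.asarray(score, dtype=float)
    lesion = np.asarray(lesion, dtype=float)
    n = measure.size
    if not (score.size == n and lesion.size == n):
        raise AssociationError("measure, score and lesion must be aligned")
    if n < 4:
        raise AssociationError(f"need n >= 4 observations, got {n}")
    if np.any(~np.isfinite(measure)) or np.any(~np.isfinite(score)) or np.any(~np.isfinite(lesion)):
        raise AssociationError("inputs contain missing or non-finite values")
    zy = _zscore(measure, measure_name or "measure")
    zx = _zscore(score, network or "score")
    zl = _zscore(lesion, "lesion")
    design = sm.add_constant(np.column_stack([zx, zl]))
    fit = sm.OLS(zy, design).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    pval = float(fit.pvalues[1])
    pr = partial_correlation(zx, zy, zl)
    simple_r = float(np.corrcoef(zx, zy)[0, 1])
    vifs = vif(pd.DataFrame({"score": zx, "lesion": zl}), warn_threshold=vif_warn)
    return RegressionResult(
        network=network,
        measure=measure_name,
        partial_r=pr,
        beta=beta,
        se=se,
        p_value=pval,
        simple_r=simple_r,
        vif_score=float(vifs["score"]),
        vif_lesion=float(vifs["lesion"]),
        n=n,
    )


def network_lesion_percent(
    lesion_fractions: pd.DataFrame,
    netdef: NetworkDefinition,
    volumes: pd.Series,
    membership: str = "continuous",
) -> pd.Series:
    """Percent lesioned tissue in a network, per participant.

    ``lesion_fractions`` is participants x regions with values in [0, 1].
    Node membership m_r is the max |composite weight| over edges incident to
    r — either over all edges (``continuous``, default) or over the reported
    (thresholded) edges only.  percent = 100 * sum(m v l) / sum(m v).
    """
    vals = lesion_fractions.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise AssociationError("lesion fractions must lie in [0, 1]")
    if membership == "continuous":
        weights = netdef.weights
    elif membership == "thresholded":
        weights = pd.Series(0.0, index=netdef.weights.index)
        for _, row in netdef.reported.iterrows():
            weights[row["edge"]] = row["weight"]
    else:
        raise AssociationError(f"unknown membership rule {membership!r}")
    m = pd.Series(0.0, index=lesion_fractions.columns)
    for edge, w in weights.items():
        a, b = split_edge(edge)
        for r in (a, b):
            if r in m.index:
                m[r] = max(m[r], abs(float(w)))
    if (m == 0).all():
        raise AssociationError(f"network {netdef.network!r} has all-zero node membership")
    v = volumes.reindex(lesion_fractions.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(v)):
        missing = [c for c in lesion_fractions.columns if c not in volumes.index]
        raise AssociationError(f"volumes missing for regions: {missing}")
    mv = m.to_numpy() * v
    percent = 100.0 * (vals @ mv) / mv.sum()
    return pd.Series(percent, index=lesion_fractions.index, name=netdef.network)


def build_table(
    scores: pd.DataFrame,
    measures: pd.DataFrame,
    lesion_percents: pd.DataFrame,
    vif_warn: float = 10.0,
) -> AssociationTable:
    """Full networks x measures association grid with best-network flags.

    ``scores``: participants x networks; ``measures``: participants x the five
    ratios; ``lesion_percents``: participants x networks (each network's own
    lesion covariate).  All three must share the participant index.
    """
    if not (scores.index.equals(measures.index) and scores.index.equals(lesion_percents.index)):
        raise AssociationError("participants are misaligned across scores/measures/lesions")
    if list(lesion_percents.columns) != list(scores.columns):
        raise AssociationError("lesion percent columns must match the network list")
    unknown = [m for m in measures.columns if m not in METRICS]
    if unknown:
        raise AssociationError(f"unknown measures: {unknown}")
    rows = []
    for network in scores.columns:
        for measure in measures.columns:
            res = fit_association(
                measures[measure].to_numpy(),
                scores[network].to_numpy(),
                lesion_percents[network].to_numpy(),
                network=network,
                measure_name=measure,
                vif_warn=vif_warn,
            )
            rows.append(res.__dict__)
    cells = pd.DataFrame(rows)

    def _best(col: str) -> dict[str, str]:
        best = {}
        for measure in measures.columns:
            sub = cells[cells["measure"] == measure]
            top = sub[col].abs().max()
            winners = sub[sub[col].abs() >= top - 1e-15]["network"].tolist()
            # ties -> lowest network index (column order)
            ordered = [nw for nw in scores.columns if nw in winners]
            if len(winners) > 1:
                logger.warning("measure %s: tie on |%s| among %s; flagging %s", measure, col, winners, ordered[0])
            best[measure] = ordered[0]
        return best

    best = _best("partial_r")
    best_unc = _best("simple_r")
    consistent = best == best_unc
    logger.info(
        "best-network flags %s with vs. without lesion adjustment (%s / %s)",
        "consistent" if consistent else "NOT consistent",
        best,
        best_unc,
    )
    cells["best_flag"] = [
        best[row.measure] == row.network for row in cells.itertuples()
    ]
    return AssociationTable(
        cells=cells,
        best_network=best,
        best_network_uncontrolled=best_unc,
        consistent_with_unadjusted=consistent,
    )
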