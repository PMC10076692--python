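"""End-to-end orchestration: cohort inputs -> association table.

Stages: grip-metric extraction (or planted ratios when no trials exist),
connectome symmetrization + correction + cohort assembly, two-level factor
analysis, per-network lesion covariates, and the association grid.  Each
stage is also callable on its own from the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .association import AssociationTable, build_table, network_lesion_percent
from .config import RunConfig
from .connectome import assemble_cohort, correct, symmetrize
from .factor import (
    FactorModel,
    NetworkDefinition,
    SecondLevelModel,
    composite_edge_weights,
    first_level,
    second_level,
)
from .grip import METRICS, summarize_participant
from .simulate import CohortData

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    ratios: pd.DataFrame  # participants x 5 measures
    edge_table: pd.DataFrame  # participants x edges (corrected weights)
    second: SecondLevelModel
    networks: dict[str, NetworkDefinition]
    lesion_percents: pd.DataFrame  # participants x networks
    association: AssociationTable


def extract_ratios(cohort: CohortData, config: RunConfig) -> pd.DataFrame:
    """Five performance ratios per participant, from trials when available."""
    if cohort.trials:
        rows = {}
        for participant in cohort.participants:
            _, _, ratios = summarize_participant(
                cohort.trials[participant], participant, config.grip
            )
            rows[participant] = ratios.ratios
        out = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRICS))
        out = out.astype(float)
        out.index.name = "participant"
        return out
    if cohort.truth is None:
        raise ValueError("cohort has neither trials nor planted ratios")
    logger.info("no trials in cohort; using planted ground-truth ratios")
    return cohort.truth.true_ratios.copy()


def build_edge_table(cohort: CohortData, config: RunConfig) -> pd.DataFrame:
    volumes = cohort.volumes
    matrices = {}
    for participant, raw in cohort.raw_counts.items():
        sym = symmetrize(raw)
        matrices[participant] = correct(
            sym,
            cohort.distances,
            volumes,
            alpha=config.connectome.alpha,
            beta=config.connectome.beta,
            participant=participant,
        )
    return assemble_cohort({p: matrices[p] for p in cohort.participants})


def factorize(edge_table: pd.DataFrame, region_names: list[str], config: RunConfig) -> SecondLevelModel:
    factor_config = replace(config.factor, seed=config.seed)
    first = first_level(edge_table, region_names, factor_config)
    return second_level(first, factor_config)


def network_definitions(
    second: SecondLevelModel, region_names: list[str], config: RunConfig
) -> dict[str, NetworkDefinition]:
    return {
        name: composite_edge_weights(
            second,
            name,
            region_names,
            threshold=config.association.edge_weight_threshold,
            top_n=config.association.top_edges,
            combine=config.association.composite_combine,
        )
        for name in second.network_names
    }


def lesion_covariates(
    cohort: CohortData, networks: dict[str, NetworkDefinition], config: RunConfig
) -> pd.DataFrame:
    cols = {
        name: network_lesion_percent(
            cohort.lesion_fractions,
            netdef,
            cohort.volumes,
            membership=config.association.lesion_membership,
        )
        for name, netdef in networks.items()
    }
    return pd.DataFrame(cols).loc[cohort.participants]


def run_pipeline(cohort: CohortData, config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    ratios = extract_ratios(cohort, config)
    edge_table = build_edge_table(cohort, config)
    region_names = [r.name for r in cohort.regions]
    second = factorize(edge_table, region_names, config)
    networks = network_definitions(second, region_names, config)
    lesion_percents = lesion_covariates(cohort, networks, config)
    association = build_table(
        second.scores.loc[cohort.participants],
        ratios.loc[cohort.participants],
        lesion_percents,
        vif_warn=config.association.vif_warn,
    )
    return PipelineResult(
        ratios=ratios,
        edge_table=edge_table,
        second=second,
        networks=networks,
        lesion_percents=lesion_percents,
        association=association,
    )
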