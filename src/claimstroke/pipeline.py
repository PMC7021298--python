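"""End-to-end convenience pipeline: claims table → validated metrics."""

from __future__ import annotations

import dataclasses

import pandas as pd

from .catalog import Catalog, default_catalog
from .claims import (
    LinkageResult,
    apply_washout,
    build_episodes,
    link_registry,
    read_claims,
    read_registry,
)
from .identifiers import IdentifierVector, extract_identifier_vector
from .model import AdmissionEpisode
from .ruleset import ClassificationResult, DecisionTree, FlowAudit, classify_dataset, default_ruleset
from .metrics import validation_report


@dataclasses.dataclass
class PipelineResult:
    episodes: list[AdmissionEpisode]
    linkage: LinkageResult
    vectors: dict[str, IdentifierVector]
    calls: list[ClassificationResult]
    audit: FlowAudit
    report: dict


def run_pipeline(
    claims: pd.DataFrame | str,
    registry: pd.DataFrame | str,
    *,
    catalog: Catalog | None = None,
    ruleset: DecisionTree | None = None,
    washout_days: int | None = None,
    split_ratio: float = 0.7,
    split_seed: int = 0,
) -> PipelineResult:
    """Episodes → washout → linkage → flags → classification → metrics."""
    catalog = catalog or default_catalog()
    ruleset = ruleset or default_ruleset()
    lines = read_claims(claims)
    episodes = apply_washout(build_episodes(lines), washout_days=washout_days)
    linkage = link_registry(episodes, read_registry(registry))
    vectors = {
        ep.episode_id: extract_identifier_vector(ep, catalog) for ep in episodes
    }
    labels = {le.episode_id: le.true_ais for le in linkage.linked}
    calls, audit = classify_dataset(
        (
            (ep.episode_id, ep.principal_dx, vectors[ep.episode_id])
            for ep in episodes
        ),
        ruleset,
        labels=labels,
    )
    report = validation_report(calls, labels, ratio=split_ratio, seed=split_seed)
    return PipelineResult(
        episodes=episodes,
        linkage=linkage,
        vectors=vectors,
        calls=calls,
        audit=audit,
        report=report,
    )
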