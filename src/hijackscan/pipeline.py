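"""End-to-end orchestration of the disruption-detection pipeline."""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd

from .candidates import (
    CandidateGene,
    call_candidates,
    gene_loci_from_interactions,
    stage_counts,
)
from .config import PipelineConfig
from .expression import (
    CountMatrix,
    NormalizedMatrix,
    call_outliers,
    gene_stats,
    median_of_ratios,
)
from .genome import Breakpoint, PromoterInteraction
from .mapping import DisruptionEvent, disrupted_gene_donor_table, map_disruptions
from .survival import SurvivalRecord, survival_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    events: list[DisruptionEvent]
    normalized: NormalizedMatrix
    outlier_calls: pd.DataFrame
    candidates: list[CandidateGene]
    screened: list[CandidateGene]
    counts_summary: dict[str, int] = field(default_factory=dict)

    @property
    def significant(self) -> list[CandidateGene]:
        return [
            c for c in self.screened
            if c.survival is not None and c.survival.significant
        ]


def run_pipeline(
    breakpoints: Sequence[Breakpoint],
    interactions: Sequence[PromoterInteraction],
    counts: CountMatrix,
    survival_records: Sequence[SurvivalRecord] | None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Map disruptions, call IQR outliers over the configured donor scope,
    apply the recurrence filter, and (when survival data are supplied) run
    the median-split log-rank screen with BH correction."""
    config = config or PipelineConfig()
    events = map_disruptions(
        breakpoints, interactions, flank_bp=config.flank_bp,
        mode=config.disruption_mode,
    )
    norm = median_of_ratios(counts)

    if config.stats_donor_scope == "sv_donors":
        sv_donors = {bp.donor_id for bp in breakpoints}
        scope = [d for d in norm.values.columns if d in sv_donors]
    else:
        scope = list(norm.values.columns)
    stats = gene_stats(norm, scope)
    calls = call_outliers(
        norm, stats,
        k_primary=config.k_primary,
        k_recurrence=config.k_recurrence,
        min_norm_expr=config.min_norm_expr,
        donor_scope=scope,
        directional=config.directional,
    )

    table = disrupted_gene_donor_table(events)
    loci = gene_loci_from_interactions(interactions)
    cands = call_candidates(table, calls, config, gene_loci=loci)
    counts_summary = stage_counts(events, calls, cands)
    counts_summary["n_breakpoints"] = len(breakpoints)
    logger.info("pipeline funnel: %s", counts_summary)

    screened: list[CandidateGene] = []
    if survival_records:
        screened = survival_screen(cands, norm, survival_records, config)
    return PipelineResult(
        config=config,
        events=events,
        normalized=norm,
        outlier_calls=calls,
        candidates=cands,
        screened=screened,
        counts_summary=counts_summary,
    )
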