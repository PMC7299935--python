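"""Recurrence-filtered candidate calling.

A gene becomes a candidate when

1. at least one donor carries both a disrupting breakpoint for the gene and a
   primary expression outlier (>2 IQR deviation, normalized expression >10 by
   default), and
2. enough additional donors (``min_recurrent_donors`` total, primary donor
   included) carry a *similar* disruption — by default one sharing a disrupted
   PIR anchor with a primary donor's event — together with at least the
   recurrence-level expression change (>1 IQR, same expression floor).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .genome import GenomicInterval, PromoterInteraction
from .mapping import DisruptionEvent


@dataclass
class CandidateGene:
    """One row of the candidate table: a gene, its disrupted anchors, and the
    donors supporting it."""

    gene_id: str
    gene_locus: GenomicInterval | None
    anchors: frozenset[GenomicInterval]
    primary_donors: frozenset[str]
    recurrent_donors: frozenset[str]
    survival: "object | None" = None  # SurvivalTestResult, attached later

    @property
    def n_donors(self) -> int:
        return len(self.recurrent_donors)


def gene_loci_from_interactions(
    interactions: Iterable[PromoterInteraction],
) -> dict[str, GenomicInterval]:
    """Promoter locus per gene: the min-max span of its bait fragments.

    The pipeline carries no external gene model, so the bait (promoter)
    fragments of a gene's interactions stand in for its locus.
    """
    acc: dict[str, list[GenomicInterval]] = {}
    for pi in interactions:
        for g in pi.gene_ids:
            acc.setdefault(g, []).append(pi.bait)
    loci = {}
    for g, baits in acc.items():
        chroms = {b.chrom for b in baits}
        if len(chroms) > 1:  # ambiguous promoter annotation; no single locus
            loci[g] = None
            continue
        loci[g] = GenomicInterval(
            baits[0].chrom, min(b.start for b in baits), max(b.end for b in baits)
        )
    return loci


def call_candidates(
    gene_donor_table: Mapping[str, set[tuple[str, GenomicInterval]]],
    outlier_calls: pd.DataFrame,
    config: PipelineConfig,
    gene_loci: Mapping[str, GenomicInterval] | None = None,
) -> list[CandidateGene]:
    """Apply the primary-outlier and anchor-sharing recurrence filters.

    ``outlier_calls`` is the long-format frame from
    :func:`hijackscan.expression.call_outliers`, computed over the donor
    scope the configuration declares.
    """
    config.validate()
    primary_pairs = set(
        map(
            tuple,
            outlier_calls.loc[
                outlier_calls["passes_primary"], ["gene_id", "donor_id"]
            ].values,
        )
    )
    recurrence_pairs = set(
        map(
            tuple,
            outlier_calls.loc[
                outlier_calls["passes_recurrence"], ["gene_id", "donor_id"]
            ].values,
        )
    )

    out: list[CandidateGene] = []
    for gene_id in sorted(gene_donor_table):
        donor_anchors = gene_donor_table[gene_id]
        primary_donors = {
            d for d, _ in donor_anchors if (gene_id, d) in primary_pairs
        }
        if not primary_donors:
            continue
        primary_anchor_set = {
            a for d, a in donor_anchors if d in primary_donors
        }
        recurrent = set(primary_donors)
        for donor, anchor in donor_anchors:
            if donor in recurrent:
                continue
            if (gene_id, donor) not in recurrence_pairs:
                continue
            if config.anchor_match == "shared" and anchor not in primary_anchor_set:
                continue
            recurrent.add(donor)
        if len(recurrent) < config.min_recurrent_donors:
            continue
        anchors = frozenset(
            a for d, a in donor_anchors if d in recurrent
        )
        out.append(
            CandidateGene(
                gene_id=gene_id,
                gene_locus=(gene_loci or {}).get(gene_id),
                anchors=anchors,
                primary_donors=frozenset(primary_donors),
                recurrent_donors=frozenset(recurrent),
            )
        )
    return out


def stage_counts(
    events: Iterable[DisruptionEvent],
    outlier_calls: pd.DataFrame,
    candidates: Iterable[CandidateGene],
) -> dict[str, int]:
    """The four funnel numbers: disrupted interactions (distinct donor ×
    interaction hits), disrupted genes, genes with both a disruption and a
    primary outlier in the same donor, and final candidates."""
    events = list(events)
    disrupted_pairs = {(e.donor_id, e.interaction_id) for e in events}
    disrupted_genes = {e.gene_id for e in events}
    primary_pairs = set(
        map(
            tuple,
            outlier_calls.loc[
                outlier_calls["passes_primary"], ["gene_id", "donor_id"]
            ].values,
        )
    )
    genes_with_primary = {
        e.gene_id for e in events if (e.gene_id, e.donor_id) in primary_pairs
    }
    return {
        "n_disrupted_interactions": len(disrupted_pairs),
        "n_disrupted_genes": len(disrupted_genes),
        "n_genes_with_primary_outlier_and_disruption": len(genes_with_primary),
        "n_candidates": len(list(candidates)),
    }
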