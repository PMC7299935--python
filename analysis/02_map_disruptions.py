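#!/usr/bin/env python
"""Intersect the cohort's flanked breakpoints with the promoter interactome.

Reads results/cohort/ (run 01_simulate_cohort.py first), maps disruptions
in the default span mode with the ±50 bp flank, and writes the event table
to results/disruption_events.tsv.
"""

from pathlib import Path

from hijackscan import PipelineConfig, map_disruptions
from hijackscan import io as hio
from hijackscan.mapping import events_to_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    bps = hio.read_breakpoints(ROOT / "cohort" / "breakpoints.tsv")
    inters = hio.read_interactions(ROOT / "cohort" / "interactions.tsv")
    events = map_disruptions(bps, inters, flank_bp=cfg.flank_bp,
                             mode=cfg.disruption_mode)
    out = ROOT / "disruption_events.tsv"
    events_to_table(events).to_csv(out, sep="\t", index=False)
    n_pairs = len({(e.donor_id, e.interaction_id) for e in events})
    n_genes = len({e.gene_id for e in events})
    print(f"{len(bps)} breakpoints x {len(inters)} interactions "
          f"(flank ±{cfg.flank_bp} bp, {cfg.disruption_mode} mode)")
    print(f"-> {n_pairs} disrupted donor-interaction pairs touching "
          f"{n_genes} genes; events -> {out}")


if __name__ == "__main__":
    main()
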