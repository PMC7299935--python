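"""Published candidate table from a genome-wide CLL enhancer-hijacking screen.

Six genes whose promoter interactions were disrupted by breakpoints in a CLL
cohort, with a concordant expression change in the affected donors and a
survival association in the combined cohorts (log-rank p and BH-adjusted p
for overall survival). This table serves as reference input for the
FDR-threshold filter and for worked examples; the ELP4 row reports multiple
disrupted anchors and carries no single anchor coordinate.
"""

from __future__ import annotations

import pandas as pd

from .genome import GenomicInterval
from .io import parse_region

_ROWS = [
    # gene, p OS, padj OS, gene locus (1-based), disrupted PIR anchor, donors
    ("TFAP2A-AS1", 0.00032, 0.01472, "chr6:10409340-10416446",
     "chr6:99589388-99626140", 3),
    ("DLX2", 0.00288, 0.04127, "chr2:172099439-172102900",
     "chr2:63042965-63063823", 2),
    ("DAD1", 0.00016, 0.00638, "chr14:22564905-22589269",
     "chr14:22370281-22410008", 2),
    ("ZNF142", 0.00521, 0.04164, "chr2:218637916-218659655",
     "chr2:128075688-128101753", 2),
    ("ELP4", 0.00354, 0.04127, "chr11:31509700-31790328", None, 3),
    ("PRMT5", 0.00413, 0.04127, "chr14:22920511-22929585",
     "chr14:22370281-22410008", 2),
]


def reference_candidates() -> pd.DataFrame:
    """The published six-row candidate table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["gene_id", "p_value_os", "padj_os", "gene_locus",
                 "disrupted_pir_anchor", "n_donors"],
    )


def reference_anchor(gene_id: str) -> GenomicInterval | None:
    """The disrupted PIR anchor of a reference gene (0-based half-open)."""
    df = reference_candidates().set_index("gene_id")
    raw = df.loc[gene_id, "disrupted_pir_anchor"]
    return parse_region(raw) if raw else None
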