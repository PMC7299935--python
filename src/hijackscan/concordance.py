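"""Cohort-concordance statistic: extreme-decile donor grouping by a focal
gene, per-gene fold changes between the groups, and a Mann-Whitney shift
test of externally supplied gene sets against the remaining genes.

This mirrors the comparison of inhibitor-responsive gene sets against
donors with extreme expression of a focal gene: the 10% highest- and
lowest-expressing donors are contrasted, every gene gets a log2 fold change
between the two groups, and a gene set's fold changes are compared with the
background's by a two-sided rank test. Fold changes are median-based with a
pseudocount — the shift test is rank-based, so only their ordering matters.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import NormalizedMatrix

#: per-side sample size at or below which the exact U distribution is used
EXACT_MAX_N = 20


@dataclass
class DecileGroups:
    focal_gene: str
    high_donors: frozenset[str]
    low_donors: frozenset[str]
    fraction: float


@dataclass
class GeneSetShiftResult:
    set_name: str
    n_set: int
    n_background: int
    u_statistic: float
    p: float
    #: sign of median(set fold changes) - median(background fold changes)
    direction: int


def decile_groups(
    expr_values: Mapping[str, float],
    fraction: float = 0.10,
    focal_gene: str = "",
) -> DecileGroups:
    """The floor(fraction*n) highest- and lowest-expressing donors.

    Donors are ordered by (value, donor_id); the lexicographic tie-break
    makes the selection deterministic and the two groups disjoint.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    k = math.floor(fraction * len(expr_values))
    if k < 1:
        raise ValueError(
            f"floor({fraction} * {len(expr_values)}) donors per group is < 1"
        )
    ordered = sorted(expr_values, key=lambda d: (expr_values[d], d))
    return DecileGroups(
        focal_gene=focal_gene,
        high_donors=frozenset(ordered[-k:]),
        low_donors=frozenset(ordered[:k]),
        fraction=fraction,
    )


def rank_fold_change(
    norm: NormalizedMatrix,
    groups: DecileGroups,
    pseudocount: float = 1.0,
    compute_p: bool = False,
) -> pd.DataFrame:
    """Per-gene log2((median_high + eps) / (median_low + eps)) between the
    extreme groups; optionally a per-gene two-sided Mann-Whitney p across
    donors. Genes with median 0 in both groups get fold change 0."""
    high = sorted(groups.high_donors)
    low = sorted(groups.low_donors)
    missing = (set(high) | set(low)) - set(norm.values.columns)
    if missing:
        raise ValueError(f"group donors not in matrix: {sorted(missing)}")
    med_high = norm.values[high].median(axis=1)
    med_low = norm.values[low].median(axis=1)
    log2fc = np.log2((med_high + pseudocount) / (med_low + pseudocount))
    out = pd.DataFrame({"log2fc": log2fc})
    out.index.name = "gene_id"
    if compute_p:
        pvals = []
        hv = norm.values[high].values
        lv = norm.values[low].values
        for i in range(len(out)):
            pvals.append(
                float(
                    stats.mannwhitneyu(
                        hv[i], lv[i], alternative="two-sided"
                    ).pvalue
                )
            )
        out["p"] = pvals
    return out


def geneset_shift_test(
    fc_table: pd.DataFrame,
    gene_set: Iterable[str],
    set_name: str = "",
) -> GeneSetShiftResult:
    """Two-sided Mann-Whitney U: the set's fold changes versus those of all
    other genes in the table.

    The exact U null distribution is enumerated when both sides have at most
    20 values and the data carry no ties; otherwise the normal approximation
    with tie correction is used.
    """
    gene_set = set(gene_set)
    in_set = fc_table.index.isin(gene_set)
    if not in_set.any():
        missing = sorted(gene_set)[:10]
        raise ValueError(
            f"gene set has no overlap with the fold-change table "
            f"(first missing: {missing})"
        )
    set_fc = fc_table.loc[in_set, "log2fc"].to_numpy(dtype=float)
    bg_fc = fc_table.loc[~in_set, "log2fc"].to_numpy(dtype=float)
    if bg_fc.size == 0:
        raise ValueError("background is empty: the set covers the whole table")

    has_ties = np.unique(np.concatenate([set_fc, bg_fc])).size < (
        set_fc.size + bg_fc.size
    )
    method = (
        "exact"
        if (set_fc.size <= EXACT_MAX_N and bg_fc.size <= EXACT_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(set_fc, bg_fc, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(set_fc) - np.median(bg_fc)))
    return GeneSetShiftResult(
        set_name=set_name,
        n_set=int(set_fc.size),
        n_background=int(bg_fc.size),
        u_statistic=float(res.statistic),
        p=float(res.pvalue),
        direction=direction,
    )
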