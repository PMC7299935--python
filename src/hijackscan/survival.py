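"""Median-split survival screen: Kaplan-Meier curves, two-group log-rank
tests, and Benjamini-Hochberg correction across the candidate family.

For each candidate gene, donors are split at the median of its normalized
expression (ties to the low group), overall survival is compared between
high and low expressors with the standard two-group log-rank test
(chi-square with 1 df, no continuity correction), and p-values are
BH-adjusted over exactly the genes tested in the run. By default the median
split is computed within each cohort separately — cohorts may use different
expression platforms, so raw values are not compared across cohorts — and
the groups are pooled for the test.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .candidates import CandidateGene
from .config import PipelineConfig
from .expression import NormalizedMatrix

logger = logging.getLogger(__name__)


class DegenerateSplitError(ValueError):
    """All expression values identical: the high group would be empty."""


class UndefinedTestError(ValueError):
    """Log-rank test undefined (no events observed)."""


@dataclass(frozen=True)
class SurvivalRecord:
    donor_id: str
    time: float
    event: bool
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")


@dataclass
class SurvivalTestResult:
    gene_id: str
    n_high: int
    n_low: int
    chi2: float
    p: float
    padj: float | None = None
    significant: bool | None = None


@dataclass
class KMCurve:
    """Right-continuous product-limit survival estimate.

    ``survival_at(t)`` evaluates the step function; ``table`` holds the
    (time, survival, at-risk) coordinates for plotting.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def median_split(expr_values: Mapping[str, float]) -> tuple[set[str], set[str]]:
    """Split donors at the median expression value; ties go to the low group."""
    if len(expr_values) < 4:
        raise ValueError(f"need >= 4 donors, got {len(expr_values)}")
    values = np.array(list(expr_values.values()), dtype=float)
    med = float(np.median(values))
    high = {d for d, v in expr_values.items() if v > med}
    if not high:
        raise DegenerateSplitError(
            "all values at or below the median; high group is empty"
        )
    low = set(expr_values) - high
    return high, low


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate; censored donors leave the risk set
    without a survival drop."""
    if not records:
        raise ValueError("need at least one record")
    durations = [r.time for r in records]
    observed = [bool(r.event) for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index)
        .to_numpy(dtype=float)
    )
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def logrank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) with 1 df."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in list(group_a) + list(group_b)):
        raise UndefinedTestError("log-rank test undefined with zero events")
    res = logrank_test(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[bool(r.event) for r in group_a],
        event_observed_B=[bool(r.event) for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def survival_screen(
    candidates: Sequence[CandidateGene],
    norm: NormalizedMatrix,
    records: Sequence[SurvivalRecord],
    config: PipelineConfig,
) -> list[CandidateGene]:
    """Attach a log-rank SurvivalTestResult to each testable candidate.

    Donors missing from either the expression matrix or the survival table
    are dropped (counts logged). Genes absent from the matrix, with a
    degenerate split, or with zero events are skipped with a warning. BH
    correction runs over exactly the genes tested.
    """
    by_donor = {r.donor_id: r for r in records}
    usable = [d for d in norm.values.columns if d in by_donor]
    n_dropped_surv = len(by_donor) - len(usable)
    n_dropped_expr = len(norm.values.columns) - len(usable)
    if n_dropped_surv or n_dropped_expr:
        logger.info(
            "survival screen: dropped %d survival-only and %d expression-only donors",
            n_dropped_surv, n_dropped_expr,
        )

    tested: list[tuple[CandidateGene, SurvivalTestResult]] = []
    for cand in candidates:
        gene = cand.gene_id
        if gene not in norm.values.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        expr = norm.values.loc[gene, usable]
        try:
            high, low = _split_donors(expr, by_donor, config)
        except (DegenerateSplitError, ValueError) as exc:
            logger.warning("gene %s: %s; skipped", gene, exc)
            continue
        rec_high = [by_donor[d] for d in sorted(high)]
        rec_low = [by_donor[d] for d in sorted(low)]
        try:
            chi2, p = logrank(rec_high, rec_low)
        except UndefinedTestError as exc:
            logger.warning("gene %s: %s; skipped", gene, exc)
            continue
        tested.append(
            (
                cand,
                SurvivalTestResult(
                    gene_id=gene, n_high=len(high), n_low=len(low), chi2=chi2, p=p
                ),
            )
        )

    if tested:
        padj = bh_adjust([res.p for _, res in tested])
        for (cand, res), adj in zip(tested, padj):
            res.padj = float(adj)
            res.significant = bool(adj < config.padj_threshold)
            cand.survival = res
    return [cand for cand, _ in tested]


def _split_donors(
    expr: pd.Series,
    by_donor: Mapping[str, SurvivalRecord],
    config: PipelineConfig,
) -> tuple[set[str], set[str]]:
    if not config.split_by_cohort:
        return median_split(expr.to_dict())
    high: set[str] = set()
    low: set[str] = set()
    cohorts: dict[str, dict[str, float]] = {}
    for donor, value in expr.items():
        cohorts.setdefault(by_donor[donor].cohort, {})[donor] = float(value)
    n_ok = 0
    for cohort, values in sorted(cohorts.items()):
        try:
            h, l = median_split(values)
        except (DegenerateSplitError, ValueError) as exc:
            logger.info("cohort %r not splittable (%s); dropped", cohort, exc)
            continue
        high |= h
        low |= l
        n_ok += 1
    if n_ok == 0:
        raise DegenerateSplitError("no cohort could be median-split")
    return high, low


def results_table(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Per-gene screen results as a flat frame."""
    rows = []
    for cand in candidates:
        res = cand.survival
        rows.append(
            {
                "gene_id": cand.gene_id,
                "n_donors": cand.n_donors,
                "n_high": res.n_high if res else None,
                "n_low": res.n_low if res else None,
                "chi2": res.chi2 if res else None,
                "p": res.p if res else None,
                "padj": res.padj if res else None,
                "significant": res.significant if res else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_donors", "n_high", "n_low", "chi2", "p", "padj",
            "significant",
        ],
    )
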