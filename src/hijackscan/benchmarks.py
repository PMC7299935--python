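"""Calibration benchmarks on synthetic cohorts: planted-candidate recovery,
log-rank type-I error and power, and gene-set shift-test calibration.

These drive the package's self-validation: each function simulates under a
stated condition, runs the corresponding pipeline stage, and returns summary
numbers. Problem sizes are chosen so each benchmark completes in seconds to
a few minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .concordance import geneset_shift_test
from .config import PipelineConfig
from .pipeline import run_pipeline
from .simulate import SimulationConfig, simulate_cohort, simulate_survival
from .survival import SurvivalRecord, logrank, median_split

#: planted-recovery study condition: strong cis-effects in a 100-donor cohort
RECOVERY_CONFIG = dict(
    n_donors=100, n_genes=1000, n_interactions=200, n_planted_genes=10,
    n_planted_donors_per_gene=2, effect_multiplier=8.0, nb_dispersion=0.1,
    n_background_breakpoints=600,
)


@dataclass
class RecoveryResult:
    recall: float
    mean_false_candidates: float
    per_seed_recall: list[float]
    per_seed_false: list[int]


def recovery_benchmark(
    n_seeds: int = 20, base_seed: int = 0, **overrides
) -> RecoveryResult:
    """Planted-candidate recall and false-candidate count over replicate
    cohorts simulated under the recovery condition."""
    params = {**RECOVERY_CONFIG, **overrides}
    recalls: list[float] = []
    falses: list[int] = []
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=base_seed + k, **params)
        cohort = simulate_cohort(cfg)
        result = run_pipeline(
            cohort["breakpoints"], cohort["interactome"], cohort["counts"],
            None,
        )
        planted = set(cohort["truth"].planted_genes)
        called = {c.gene_id for c in result.candidates}
        recalls.append(len(called & planted) / len(planted))
        falses.append(len(called - planted))
    return RecoveryResult(
        recall=float(np.mean(recalls)),
        mean_false_candidates=float(np.mean(falses)),
        per_seed_recall=recalls,
        per_seed_false=falses,
    )


def _null_survival_replicate(
    rng: np.random.Generator, n_donors: int, hazard_ratio: float,
    censoring: float = 0.3,
) -> float:
    """One median-split log-rank p under exponential survival with the given
    hazard ratio between expression groups."""
    expr = {f"D{i:03d}": float(v) for i, v in
            enumerate(rng.lognormal(3, 1, size=n_donors))}
    high, low = median_split(expr)
    base_rate = SimulationConfig().hazard_rate_base
    rates = np.array([
        base_rate * (hazard_ratio if d in high else 1.0)
        for d in sorted(expr)
    ])
    times = rng.exponential(1.0 / rates)
    if censoring > 0:
        from .simulate import _censoring_horizon

        horizon = _censoring_horizon(rates, censoring)
        censor_times = rng.uniform(0, horizon, size=n_donors)
        observed = times <= censor_times
        times = np.minimum(times, censor_times)
    else:
        observed = np.ones(n_donors, dtype=bool)
    records = [
        SurvivalRecord(donor_id=d, time=float(t), event=bool(e))
        for d, t, e in zip(sorted(expr), times, observed)
    ]
    rec_high = [r for r in records if r.donor_id in high]
    rec_low = [r for r in records if r.donor_id in low]
    return logrank(rec_high, rec_low)[1]


def logrank_type1(
    n_reps: int = 500, n_donors: int = 100, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of raw log-rank p below alpha under the null (hazard ratio
    1, expression independent of survival), with the exact binomial 99%
    acceptance band around alpha."""
    rng = np.random.default_rng([10, seed])
    pvals = np.array([
        _null_survival_replicate(rng, n_donors, hazard_ratio=1.0)
        for _ in range(n_reps)
    ])
    n_sig = int(np.sum(pvals < alpha))
    lo, hi = sps.binom.interval(0.99, n_reps, alpha)
    return {
        "fraction_significant": n_sig / n_reps,
        "n_significant": n_sig,
        "n_reps": n_reps,
        "binomial_99_band": (int(lo), int(hi)),
        "pvals": pvals,
    }


def logrank_power(
    n_reps: int = 100, n_donors: int = 200, hazard_ratio: float = 3.0,
    seed: int = 0, alpha: float = 0.05,
) -> dict:
    """Power of the median-split log-rank screen at a planted hazard ratio."""
    rng = np.random.default_rng([11, seed])
    pvals = np.array([
        _null_survival_replicate(rng, n_donors, hazard_ratio=hazard_ratio)
        for _ in range(n_reps)
    ])
    return {
        "power": float(np.mean(pvals < alpha)),
        "n_reps": n_reps,
        "pvals": pvals,
    }


def geneset_null_uniformity(
    n_reps: int = 1000, n_genes: int = 1000, set_size: int = 50, seed: int = 0
) -> dict:
    """KS uniformity of gene-set shift p-values for random sets drawn from a
    null fold-change table."""
    rng = np.random.default_rng([12, seed])
    table = pd.DataFrame(
        {"log2fc": rng.normal(size=n_genes)},
        index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene_id"),
    )
    genes = np.array(table.index)
    pvals = np.array([
        geneset_shift_test(
            table, set(rng.choice(genes, size=set_size, replace=False))
        ).p
        for _ in range(n_reps)
    ])
    return {
        "ks_p": float(sps.kstest(pvals, "uniform").pvalue),
        "n_reps": n_reps,
        "pvals": pvals,
    }


def planted_shift_p(
    n_background: int = 5000, n_set: int = 200, shift: float = 2.0,
    seed: int = 0,
) -> float:
    """Gene-set shift p for an additive fold-change shift planted on a gene
    set against a standard-normal background."""
    rng = np.random.default_rng([13, seed])
    fc = np.concatenate([
        rng.normal(loc=shift, size=n_set), rng.normal(size=n_background)
    ])
    genes = [f"S{i}" for i in range(n_set)] + [
        f"B{i}" for i in range(n_background)
    ]
    table = pd.DataFrame(
        {"log2fc": fc}, index=pd.Index(genes, name="gene_id")
    )
    return geneset_shift_test(table, {f"S{i}" for i in range(n_set)}).p
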