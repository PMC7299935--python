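"""Synthetic cohorts with planted ground truth.

Every pipeline input is emulated at configurable scale: a toy promoter
interactome with non-overlapping bait/anchor fragments, donor breakpoints
planted inside the anchors of chosen genes (background breakpoints fall
outside every interaction span), negative-binomial counts with per-donor
size factors and multiplicative cis-upregulation planted on chosen
(gene, donor) pairs, and exponential overall survival whose hazard depends
on the median-split group of a designated gene, with independent uniform
censoring calibrated to a target censoring fraction.

Default scale follows the modelled study: 92 donors with ~750 breakpoints.
Each stage draws from its own seed stream, so any stage is reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import CountMatrix, NormalizedMatrix
from .genome import Breakpoint, GenomicInterval, PromoterInteraction
from .survival import SurvivalRecord, median_split

# fixed interactome geometry (bp)
_BAIT_LEN = 5_000
_GAP_LEN = 15_000
_PIR_LEN = 20_000
_SLOT_MARGIN = 30_000
_SLOT = _BAIT_LEN + _GAP_LEN + _PIR_LEN + _SLOT_MARGIN + 10_000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_donors: int = 92
    n_genes: int = 2000
    n_interactions: int = 300
    chrom_length: int = 50_000_000
    genes_per_interaction: int = 1
    n_planted_genes: int = 10
    n_planted_donors_per_gene: int = 2
    #: fold applied to the planted gene's NB mean in planted donors
    effect_multiplier: float = 8.0
    #: NB dispersion alpha: var = mu + alpha * mu^2
    nb_dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    baseline_mean_range: tuple[float, float] = (20.0, 200.0)
    n_background_breakpoints: int = 730
    #: baseline event hazard per day (median OS ~ 3.8 years at 5e-4)
    hazard_rate_base: float = 5e-4
    #: hazard of the designated gene's high-expression group vs low
    hazard_ratio: float = 2.0
    censoring_fraction_target: float = 0.3
    #: gene whose median split drives survival; default: first planted gene
    survival_gene: str | None = None

    def __post_init__(self) -> None:
        if min(
            self.n_donors, self.n_genes, self.chrom_length,
            self.genes_per_interaction,
        ) <= 0:
            raise ValueError("counts must be positive")
        if self.n_interactions < 0 or self.n_background_breakpoints < 0:
            raise ValueError("counts must be non-negative")
        if self.effect_multiplier < 1:
            raise ValueError("effect_multiplier must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.censoring_fraction_target < 1):
            raise ValueError("censoring_fraction_target must lie in [0, 1)")
        if self.n_interactions * self.genes_per_interaction > self.n_genes:
            raise ValueError("not enough genes to annotate every interaction")
        if self.chrom_length < _SLOT:
            raise ValueError(
                f"chrom_length must be >= {_SLOT} to fit one interaction slot"
            )
        if self.n_planted_genes > self.n_interactions:
            raise ValueError("cannot plant more genes than interactions")
        if self.n_planted_donors_per_gene > self.n_donors:
            raise ValueError("cannot plant more donors per gene than donors")

    def donor_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_donors)]

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated cohort."""

    planted_pairs: list[tuple[str, str]]  # (gene_id, donor_id)
    planted_anchors: dict[str, GenomicInterval]  # gene -> PIR anchor
    planted_interactions: dict[str, str]  # gene -> interaction_id
    survival_gene: str
    survival_groups: dict[str, str] = field(default_factory=dict)

    @property
    def planted_genes(self) -> list[str]:
        return list(dict.fromkeys(g for g, _ in self.planted_pairs))


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


def simulate_interactome(cfg: SimulationConfig) -> list[PromoterInteraction]:
    """Non-overlapping bait/PIR fragment pairs tiled along toy chromosomes.

    Layout is deterministic; each interaction is annotated with
    ``genes_per_interaction`` consecutive gene IDs (an anchor shared by
    several genes models multi-gene regulatory loci)."""
    rng = _rng(cfg, 0)
    per_chrom = cfg.chrom_length // _SLOT
    interactions: list[PromoterInteraction] = []
    gene_ids = cfg.gene_ids()
    for i in range(cfg.n_interactions):
        chrom = f"chr{i // per_chrom + 1}"
        offset = (i % per_chrom) * _SLOT + _SLOT_MARGIN
        bait = GenomicInterval(chrom, offset, offset + _BAIT_LEN)
        pir_start = offset + _BAIT_LEN + _GAP_LEN
        pir = GenomicInterval(chrom, pir_start, pir_start + _PIR_LEN)
        genes = tuple(
            gene_ids[i * cfg.genes_per_interaction + j]
            for j in range(cfg.genes_per_interaction)
        )
        interactions.append(
            PromoterInteraction(
                interaction_id=f"INT{i:05d}",
                gene_ids=genes,
                bait=bait,
                pir=pir,
                score=float(np.round(rng.uniform(5.0, 15.0), 3)),
            )
        )
    return interactions


def plan_truth(
    cfg: SimulationConfig, interactome: list[PromoterInteraction]
) -> SyntheticTruth:
    """Choose planted interactions, one planted gene each, and the planted
    donors per gene (distinct within a gene)."""
    rng = _rng(cfg, 1)
    donors = cfg.donor_ids()
    planted_pairs: list[tuple[str, str]] = []
    planted_anchors: dict[str, GenomicInterval] = {}
    planted_inter: dict[str, str] = {}
    if cfg.n_planted_genes and interactome:
        chosen = rng.choice(
            len(interactome), size=cfg.n_planted_genes, replace=False
        )
        for idx in sorted(chosen):
            pi = interactome[idx]
            gene = pi.gene_ids[int(rng.integers(len(pi.gene_ids)))]
            planted_anchors[gene] = pi.pir
            planted_inter[gene] = pi.interaction_id
            picked = rng.choice(
                cfg.n_donors, size=cfg.n_planted_donors_per_gene, replace=False
            )
            for d in sorted(picked):
                planted_pairs.append((gene, donors[d]))
    survival_gene = cfg.survival_gene or (
        planted_pairs[0][0] if planted_pairs else cfg.gene_ids()[0]
    )
    return SyntheticTruth(
        planted_pairs=planted_pairs,
        planted_anchors=planted_anchors,
        planted_interactions=planted_inter,
        survival_gene=survival_gene,
    )


def simulate_breakpoints(
    cfg: SimulationConfig,
    interactome: list[PromoterInteraction],
    truth: SyntheticTruth,
) -> list[Breakpoint]:
    """Planted breakpoints uniform inside their gene's PIR anchor; background
    breakpoints uniform outside every interaction span, random donors."""
    rng = _rng(cfg, 2)
    donors = cfg.donor_ids()
    bps: list[Breakpoint] = []
    for gene, donor in truth.planted_pairs:
        anchor = truth.planted_anchors[gene]
        pos = int(rng.integers(anchor.start, anchor.end))
        bps.append(Breakpoint(donor_id=donor, chrom=anchor.chrom, pos=pos,
                              sv_type="BND"))

    # complement of the interaction spans, per chromosome
    spans: dict[str, list[tuple[int, int]]] = {}
    for pi in interactome:
        lo = min(pi.bait.start, pi.pir.start)
        hi = max(pi.bait.end, pi.pir.end)
        spans.setdefault(pi.bait.chrom, []).append((lo, hi))
    chroms = sorted(spans) or ["chr1"]
    gaps: list[tuple[str, int, int]] = []
    for chrom in chroms:
        cursor = 0
        for lo, hi in sorted(spans.get(chrom, [])):
            if lo > cursor:
                gaps.append((chrom, cursor, lo))
            cursor = max(cursor, hi)
        if cursor < cfg.chrom_length:
            gaps.append((chrom, cursor, cfg.chrom_length))
    if cfg.n_background_breakpoints and not gaps:
        raise ValueError("no genomic space outside interaction spans")
    if cfg.n_background_breakpoints:
        lengths = np.array([hi - lo for _, lo, hi in gaps], dtype=float)
        picks = rng.choice(
            len(gaps), size=cfg.n_background_breakpoints,
            p=lengths / lengths.sum(),
        )
        for gi in picks:
            chrom, lo, hi = gaps[gi]
            pos = int(rng.integers(lo, hi))
            donor = donors[int(rng.integers(cfg.n_donors))]
            bps.append(Breakpoint(donor_id=donor, chrom=chrom, pos=pos,
                                  sv_type="BND"))
    return bps


def simulate_counts(cfg: SimulationConfig, truth: SyntheticTruth) -> CountMatrix:
    """NB counts with mean sf_d * q_g * m_gd and dispersion alpha, where
    m_gd = effect_multiplier for planted (gene, donor) pairs and 1 otherwise.
    Size factors and baseline means are log-uniform in their ranges."""
    rng = _rng(cfg, 3)
    genes = cfg.gene_ids()
    donors = cfg.donor_ids()
    sf = np.exp(rng.uniform(*np.log(cfg.size_factor_range), size=cfg.n_donors))
    q = np.exp(rng.uniform(*np.log(cfg.baseline_mean_range), size=cfg.n_genes))
    mu = np.outer(q, sf)
    gene_pos = {g: i for i, g in enumerate(genes)}
    donor_pos = {d: j for j, d in enumerate(donors)}
    for gene, donor in truth.planted_pairs:
        mu[gene_pos[gene], donor_pos[donor]] *= cfg.effect_multiplier
    alpha = cfg.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    return CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=genes, columns=donors)
    )


def _censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Uniform-censoring horizon m with expected censored fraction == target.

    For T ~ Exp(rate) and C ~ U(0, m), P(C < T) = (1 - exp(-rate*m)) / (rate*m),
    averaged over donors; monotone decreasing in m."""

    def expected_censored(m: float) -> float:
        x = rates * m
        return float(np.mean(np.expm1(-x) / -x))

    lo, hi = 1e-9, 1.0
    while expected_censored(hi) > target:
        hi *= 2
        if hi > 1e12:
            raise RuntimeError("could not bracket censoring horizon")
    return brentq(lambda m: expected_censored(m) - target, lo, hi)


def simulate_survival(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    norm: NormalizedMatrix,
    cohort: str = "SYNTH",
) -> list[SurvivalRecord]:
    """Exponential overall survival with hazard ratio between the designated
    gene's median-split expression groups, plus independent uniform
    censoring. Fills ``truth.survival_groups``."""
    gene = truth.survival_gene
    if gene not in norm.values.index:
        raise ValueError(f"designated survival gene {gene} absent from matrix")
    expr = norm.values.loc[gene].to_dict()
    high, low = median_split(expr)
    truth.survival_groups = {d: ("high" if d in high else "low") for d in expr}
    donors = list(norm.values.columns)
    rates = np.array(
        [
            cfg.hazard_rate_base
            * (cfg.hazard_ratio if d in high else 1.0)
            for d in donors
        ]
    )
    rng = _rng(cfg, 4)
    times = rng.exponential(1.0 / rates)
    if cfg.censoring_fraction_target > 0:
        horizon = _censoring_horizon(rates, cfg.censoring_fraction_target)
        censor = rng.uniform(0, horizon, size=len(donors))
        observed = times <= censor
        times = np.minimum(times, censor)
    else:
        observed = np.ones(len(donors), dtype=bool)
    return [
        SurvivalRecord(
            donor_id=d, time=float(t), event=bool(e), cohort=cohort
        )
        for d, t, e in zip(donors, times, observed)
    ]


def simulate_cohort(cfg: SimulationConfig) -> dict:
    """Run every generator stage; returns a dict with interactome,
    breakpoints, counts, normalized matrix, survival records, and truth."""
    from .expression import median_of_ratios

    interactome = simulate_interactome(cfg)
    truth = plan_truth(cfg, interactome)
    breakpoints = simulate_breakpoints(cfg, interactome, truth)
    counts = simulate_counts(cfg, truth)
    norm = median_of_ratios(counts)
    records = simulate_survival(cfg, truth, norm)
    return {
        "config": cfg,
        "interactome": interactome,
        "breakpoints": breakpoints,
        "counts": counts,
        "normalized": norm,
        "survival": records,
        "truth": truth,
    }


def write_cohort(cohort: dict, outdir) -> dict[str, Path]:
    """Write the five pipeline input files plus the truth JSON."""
    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "breakpoints": outdir / "breakpoints.tsv",
        "interactions": outdir / "interactions.tsv",
        "counts": outdir / "counts.tsv",
        "survival": outdir / "survival.tsv",
        "genesets": outdir / "genesets.gmt",
        "truth": outdir / "truth.json",
    }
    hio.write_breakpoints(cohort["breakpoints"], paths["breakpoints"])
    hio.write_interactions(cohort["interactome"], paths["interactions"])
    hio.write_counts(cohort["counts"], paths["counts"])
    hio.write_survival(cohort["survival"], paths["survival"])

    truth: SyntheticTruth = cohort["truth"]
    with open(paths["genesets"], "w") as fh:
        fh.write(
            "planted_genes\tsynthetic planted cis-upregulated genes\t"
            + "\t".join(truth.planted_genes)
            + "\n"
        )
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted_pairs": truth.planted_pairs,
                "planted_anchors": {
                    g: a.region_string() for g, a in truth.planted_anchors.items()
                },
                "planted_interactions": truth.planted_interactions,
                "survival_gene": truth.survival_gene,
                "survival_groups": truth.survival_groups,
                "config": dataclasses.asdict(cohort["config"]),
            },
            fh,
            indent=2,
        )
    return paths
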