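import json

import numpy as np
import pytest

from hijackscan import (
    SimulationConfig,
    map_disruptions,
    median_of_ratios,
    plan_truth,
    simulate_breakpoints,
    simulate_cohort,
    simulate_counts,
    simulate_interactome,
    simulate_survival,
    write_cohort,
)
from hijackscan import io as hio
from hijackscan.genome import interaction_span, overlaps


@pytest.fixture
def small_cfg():
    return SimulationConfig(
        seed=7, n_donors=20, n_genes=120, n_interactions=30,
        n_planted_genes=4, n_background_breakpoints=60,
    )


class TestInteractome:
    def test_same_seed_reproduces_identical_output(self, small_cfg):
        assert simulate_interactome(small_cfg) == simulate_interactome(small_cfg)

    def test_fragments_never_overlap(self, small_cfg):
        inters = simulate_interactome(small_cfg)
        frags = [pi.bait for pi in inters] + [pi.pir for pi in inters]
        for i, a in enumerate(frags):
            for b in frags[i + 1:]:
                assert not overlaps(a, b)

    def test_shared_anchor_annotation(self):
        cfg = SimulationConfig(
            n_donors=10, n_genes=60, n_interactions=20,
            genes_per_interaction=2, n_planted_genes=2,
        )
        inters = simulate_interactome(cfg)
        assert all(len(pi.gene_ids) == 2 for pi in inters)
        all_genes = [g for pi in inters for g in pi.gene_ids]
        assert len(all_genes) == len(set(all_genes))

    def test_zero_interactions_empty(self):
        cfg = SimulationConfig(
            n_donors=10, n_genes=10, n_interactions=0, n_planted_genes=0,
        )
        assert simulate_interactome(cfg) == []

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=5, n_interactions=10)
        with pytest.raises(ValueError):
            SimulationConfig(effect_multiplier=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=1000)


class TestBreakpoints:
    def test_planted_breakpoints_hit_their_gene_in_anchor_mode(self, small_cfg):
        inters = simulate_interactome(small_cfg)
        truth = plan_truth(small_cfg, inters)
        bps = simulate_breakpoints(small_cfg, inters, truth)
        events = map_disruptions(bps, inters, flank_bp=50, mode="anchor")
        hit_pairs = {(e.gene_id, e.donor_id) for e in events}
        for pair in truth.planted_pairs:
            assert tuple(pair) in hit_pairs

    def test_background_only_simulation_maps_nowhere(self, small_cfg):
        cfg = SimulationConfig(
            **{**small_cfg.__dict__, "n_planted_genes": 0}
        )
        inters = simulate_interactome(cfg)
        truth = plan_truth(cfg, inters)
        bps = simulate_breakpoints(cfg, inters, truth)
        assert truth.planted_pairs == []
        assert map_disruptions(bps, inters, flank_bp=50, mode="anchor") == []
        # background breakpoints fall outside every interaction span
        spans = [interaction_span(pi) for pi in inters]
        for bp in bps:
            assert not any(s.contains(bp.chrom, bp.pos) for s in spans)

    def test_cohort_scale_round_trips_through_reader(self, tmp_path):
        """At study scale (92 donors, ~750 breakpoints) the written file
        reads back with identical counts."""
        cfg = SimulationConfig(seed=3)
        inters = simulate_interactome(cfg)
        truth = plan_truth(cfg, inters)
        bps = simulate_breakpoints(cfg, inters, truth)
        assert len(bps) == cfg.n_background_breakpoints + len(truth.planted_pairs)
        assert len({b.donor_id for b in bps}) <= 92
        path = tmp_path / "bp.tsv"
        hio.write_breakpoints(bps, path)
        assert len(hio.read_breakpoints(path)) == len(
            {(b.donor_id, b.chrom, b.pos) for b in bps}
        )


class TestCounts:
    def test_planted_effect_multiplies_the_mean(self):
        """Monte-Carlo check of the generator: the sample mean of a planted
        (gene, donor) cell over replicate draws matches
        size_factor * baseline * effect within 3 standard errors."""
        n_rep = 3000
        base = SimulationConfig(
            n_donors=4, n_genes=6, n_interactions=3, n_planted_genes=1,
            n_planted_donors_per_gene=1, n_background_breakpoints=0,
            effect_multiplier=6.0, nb_dispersion=0.1,
        )
        inters = simulate_interactome(base)
        truth = plan_truth(base, inters)
        gene, donor = truth.planted_pairs[0]
        draws = np.empty(n_rep)
        baselines = np.empty(n_rep)
        for i in range(n_rep):
            cfg = SimulationConfig(**{**base.__dict__, "seed": 10_000 + i})
            cm = simulate_counts(cfg, truth)
            draws[i] = cm.counts.loc[gene, donor]
            baselines[i] = cm.counts.loc[gene].drop(donor).mean()
        # planted cell mean is ~effect_multiplier times the same gene's
        # unplanted-donor mean (size factors shared within each replicate)
        ratio = draws.mean() / baselines.mean()
        se = draws.std(ddof=1) / np.sqrt(n_rep) / baselines.mean()
        assert abs(ratio - base.effect_multiplier) < max(
            3 * se * base.effect_multiplier, 0.5
        )

    def test_null_effect_outlier_rate_matches_background(self):
        """With effect_multiplier = 1 the planted pairs are statistically
        indistinguishable from background cells."""
        from hijackscan import call_outliers, gene_stats

        cfg = SimulationConfig(
            seed=11, n_donors=60, n_genes=400, n_interactions=80,
            n_planted_genes=20, effect_multiplier=1.0,
        )
        inters = simulate_interactome(cfg)
        truth = plan_truth(cfg, inters)
        norm = median_of_ratios(simulate_counts(cfg, truth))
        stats = gene_stats(norm, norm.values.columns)
        calls = call_outliers(norm, stats)
        planted = set(map(tuple, truth.planted_pairs))
        is_planted = calls.apply(
            lambda r: (r["gene_id"], r["donor_id"]) in planted, axis=1
        )
        rate_planted = calls.loc[is_planted, "passes_primary"].mean()
        rate_bg = calls.loc[~is_planted, "passes_primary"].mean()
        n_planted = int(is_planted.sum())
        # 3-sigma binomial band around the background rate
        band = 3 * np.sqrt(max(rate_bg, 1e-4) * (1 - rate_bg) / n_planted)
        assert abs(rate_planted - rate_bg) < max(band, 0.05)

    def test_low_dispersion_approaches_poisson(self):
        cfg = SimulationConfig(
            seed=5, n_donors=200, n_genes=50, n_interactions=10,
            n_planted_genes=0, nb_dispersion=1e-12,
            baseline_mean_range=(500.0, 501.0), size_factor_range=(1.0, 1.0 + 1e-9),
        )
        truth = plan_truth(cfg, simulate_interactome(cfg))
        cm = simulate_counts(cfg, truth)
        vmr = cm.counts.var(axis=1) / cm.counts.mean(axis=1)
        assert abs(vmr.mean() - 1.0) < 0.1


class TestSurvival:
    def _norm(self, cfg):
        truth = plan_truth(cfg, simulate_interactome(cfg))
        norm = median_of_ratios(simulate_counts(cfg, truth))
        return truth, norm

    def test_no_censoring_when_target_zero(self):
        cfg = SimulationConfig(
            seed=2, n_donors=30, n_genes=50, n_interactions=10,
            n_planted_genes=2, censoring_fraction_target=0.0,
        )
        truth, norm = self._norm(cfg)
        recs = simulate_survival(cfg, truth, norm)
        assert all(r.event for r in recs)
        assert set(truth.survival_groups.values()) == {"high", "low"}

    def test_censoring_fraction_near_target(self):
        cfg = SimulationConfig(
            seed=2, n_donors=400, n_genes=50, n_interactions=10,
            n_planted_genes=2, censoring_fraction_target=0.4,
        )
        truth, norm = self._norm(cfg)
        recs = simulate_survival(cfg, truth, norm)
        censored = np.mean([not r.event for r in recs])
        assert abs(censored - 0.4) < 0.1

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(
            seed=9, n_donors=25, n_genes=60, n_interactions=12,
            n_planted_genes=2,
        )
        truth, norm = self._norm(cfg)
        a = simulate_survival(cfg, truth, norm)
        b = simulate_survival(cfg, truth, norm)
        assert a == b


class TestCohortRoundTrip:
    def test_written_cohort_is_readable_and_consistent(self, tmp_path, small_cfg):
        cohort = simulate_cohort(small_cfg)
        paths = write_cohort(cohort, tmp_path)
        bps = hio.read_breakpoints(paths["breakpoints"])
        inters = hio.read_interactions(paths["interactions"])
        counts = hio.read_counts(paths["counts"])
        recs = hio.read_survival(paths["survival"])
        assert inters == cohort["interactome"]
        assert counts.counts.equals(cohort["counts"].counts)
        assert recs == cohort["survival"]
        assert {(b.donor_id, b.chrom, b.pos) for b in bps} == {
            (b.donor_id, b.chrom, b.pos) for b in cohort["breakpoints"]
        }
        truth = json.loads(paths["truth"].read_text())
        gene_sets = hio.read_gene_sets(paths["genesets"])
        assert gene_sets["planted_genes"] == cohort["truth"].planted_genes
        assert truth["survival_gene"] == cohort["truth"].survival_gene
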