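import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hijackscan import (
    NormalizedMatrix,
    PipelineConfig,
    SurvivalRecord,
    bh_adjust,
    km_estimate,
    logrank,
    median_split,
    survival_screen,
)
from hijackscan.candidates import CandidateGene
from hijackscan.genome import GenomicInterval
from hijackscan.survival import DegenerateSplitError, UndefinedTestError


def _records(times, events, prefix="D"):
    return [
        SurvivalRecord(donor_id=f"{prefix}{i}", time=float(t), event=bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def logrank_oracle(times_a, events_a, times_b, events_b):
    """First-principles O/E/V table over pooled event times."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a = np.asarray(events_a, bool)
    events_b = np.asarray(events_b, bool)
    event_times = np.unique(
        np.concatenate([times_a[events_a], times_b[events_b]])
    )
    observed_a = expected_a = variance = 0.0
    for t in event_times:
        n_a = np.sum(times_a >= t)
        n_b = np.sum(times_b >= t)
        n = n_a + n_b
        d_a = np.sum((times_a == t) & events_a)
        d = d_a + np.sum((times_b == t) & events_b)
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    chi2 = (observed_a - expected_a) ** 2 / variance
    return chi2


class TestMedianSplit:
    def test_even_split(self):
        high, low = median_split({"A": 1, "B": 2, "C": 3, "D": 4})
        assert high == {"C", "D"} and low == {"A", "B"}

    def test_ties_at_median_go_low(self):
        high, low = median_split({"A": 1, "B": 2, "C": 3, "D": 2})
        assert high == {"C"} and low == {"A", "B", "D"}

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            median_split({d: 5.0 for d in "ABCD"})


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        curve = km_estimate(_records([1, 2, 3, 4, 5], [0] * 5))
        assert curve.survival_at(100) == 1.0

    def test_single_event_drops_by_one_over_n(self):
        curve = km_estimate(_records([10, 20, 30, 40], [1, 0, 0, 0]))
        assert curve.survival_at(10) == pytest.approx(0.75)
        assert curve.survival_at(9.9) == 1.0

    def test_hand_computed_product_limit_with_censoring(self):
        """Events at t=1,2, censor at 1.5 among n=3:
        S(1) = 2/3, then the last at-risk donor dies at 2 -> S(2) = 0."""
        curve = km_estimate(_records([1, 1.5, 2], [1, 0, 1]))
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(1.9) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(0.0)

    def test_curve_is_monotone_nonincreasing(self, rng):
        times = rng.exponential(10, size=50)
        events = rng.random(50) < 0.7
        curve = km_estimate(_records(times, events))
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival_at(-1) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            _records([-1], [1])


class TestLogrank:
    def test_identical_groups_give_null(self):
        rec = _records([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank(rec, _records([1, 2, 3, 4], [1, 1, 0, 1], prefix="E"))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two_example(self):
        """A: events at 1,2; B: events at 3,4. O_A=2, E_A=5/6,
        V=17/36 -> chi2 = 49/17."""
        a = _records([1, 2], [1, 1], prefix="A")
        b = _records([3, 4], [1, 1], prefix="B")
        chi2, p = logrank(a, b)
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(49 / 17, df=1), rel=1e-9)
        assert chi2 == pytest.approx(
            logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1]), rel=1e-9
        )

    def test_group_label_swap_invariance(self, rng):
        a = _records(rng.exponential(5, 8), rng.random(8) < 0.8, prefix="A")
        b = _records(rng.exponential(8, 9), rng.random(9) < 0.8, prefix="B")
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0], rel=1e-9)

    def test_zero_events_undefined(self):
        with pytest.raises(UndefinedTestError):
            logrank(_records([1, 2], [0, 0]), _records([3], [0], prefix="E"))

    def test_p_matches_permutation_null(self, rng):
        """The chi-square p agrees with a 20,000-permutation group-label
        null on a random 20-donor dataset, within Monte-Carlo error."""
        n = 20
        times = rng.exponential(10, size=n)
        events = rng.random(n) < 0.8
        labels = np.array([True] * 10 + [False] * 10)
        chi2_obs, p_chi2 = logrank(
            _records(times[labels], events[labels], prefix="A"),
            _records(times[~labels], events[~labels], prefix="B"),
        )
        n_perm = 20_000
        stats = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(labels)
            stats[i] = logrank_oracle(
                times[perm], events[perm], times[~perm], events[~perm]
            )
        p_perm = float(np.mean(stats >= chi2_obs - 1e-12))
        # the chi-square reference is asymptotic: at ~16 events it is only
        # accurate to a few hundredths in p, on top of Monte-Carlo noise
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_chi2 - p_perm) < mc_err + 0.05


class TestBHAdjust:
    def test_three_equal_adjusted_values(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_direct_step_up_oracle(self, rng):
        """100 random p-vectors against the direct p*m/rank computation with
        enforced step-up monotonicity."""
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1, size=m)
            order = np.argsort(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(ranked, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                 max_size=30)
    )
    @settings(derandomize=True, max_examples=100)
    def test_bounds(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()


class TestSurvivalScreen:
    def _candidate(self, gene):
        anchor = GenomicInterval("chr1", 0, 100)
        return CandidateGene(
            gene_id=gene, gene_locus=None, anchors=frozenset([anchor]),
            primary_donors=frozenset({"D0"}),
            recurrent_donors=frozenset({"D0", "D1"}),
        )

    def test_empty_candidate_list_is_noop(self):
        donors = [f"D{i}" for i in range(6)]
        norm = NormalizedMatrix(
            values=pd.DataFrame(np.ones((1, 6)), index=["G"], columns=donors),
            size_factors=pd.Series(1.0, index=donors),
        )
        recs = _records(range(1, 7), [1] * 6)
        assert survival_screen([], norm, recs, PipelineConfig()) == []

    def test_gene_absent_from_matrix_skipped(self, rng):
        donors = [f"D{i}" for i in range(8)]
        norm = NormalizedMatrix(
            values=pd.DataFrame(rng.uniform(1, 9, (1, 8)), index=["G"],
                                columns=donors),
            size_factors=pd.Series(1.0, index=donors),
        )
        recs = _records(range(1, 9), [1] * 8)
        out = survival_screen(
            [self._candidate("MISSING"), self._candidate("G")],
            norm, recs, PipelineConfig(),
        )
        assert [c.gene_id for c in out] == ["G"]
        assert out[0].survival.padj is not None

    def test_bh_family_is_the_tested_genes(self, rng):
        donors = [f"D{i}" for i in range(20)]
        norm = NormalizedMatrix(
            values=pd.DataFrame(rng.uniform(1, 9, (5, 20)),
                                index=[f"G{k}" for k in range(5)],
                                columns=donors),
            size_factors=pd.Series(1.0, index=donors),
        )
        recs = _records(rng.exponential(10, 20), [1] * 20)
        out = survival_screen(
            [self._candidate(f"G{k}") for k in range(5)],
            norm, recs, PipelineConfig(),
        )
        pvals = [c.survival.p for c in out]
        np.testing.assert_allclose(
            [c.survival.padj for c in out], bh_adjust(pvals), atol=1e-12
        )
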