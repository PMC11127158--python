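"""Leave-one-out evaluation: oracles, CI arithmetic, curve shapes."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import mskcbr as m
from mskcbr.similarity import PairTable

from test_retrieval import brute_force_ranking


def _full_sleep_example(worked_example):
    """Worked example with a complete sleep table, usable for mutual queries."""
    model, query, cb = worked_example
    full = PairTable({
        ("Normal", "Slight"): 0.8, ("Normal", "Moderate"): 0.4, ("Normal", "Great"): 0.2,
        ("Slight", "Moderate"): 0.8, ("Slight", "Great"): 0.4, ("Moderate", "Great"): 0.6,
    })
    attrs = tuple(
        dataclasses.replace(a, local_fn=full) if a.name == "sleep_problems" else a
        for a in model.attributes
    )
    return m.SimilarityModel(attrs, name=model.name), query, cb


class TestLeaveOneOut:
    def test_two_case_base(self, default_model, cohort50):
        cb = m.CaseBase(cases=cohort50.cases[:2])
        rankings = m.leave_one_out_ranks(default_model, cb)
        assert [r.query_id for r in rankings] == list(cb.case_ids)
        assert rankings[0].case_ids == (cb.case_ids[1],)
        assert rankings[1].case_ids == (cb.case_ids[0],)
        assert rankings[0].scores == rankings[1].scores  # symmetric local functions

    def test_mutual_queries_over_extended_worked_example(self, worked_example):
        model, query, cb = _full_sleep_example(worked_example)
        extended = m.retain(cb, query)
        rankings = m.leave_one_out_ranks(model, extended)
        assert len(rankings) == 5
        for r in rankings:
            assert len(r) == 4
            assert r.query_id not in r.case_ids

    def test_single_case_rejected(self, default_model, cohort50):
        with pytest.raises(ValueError):
            m.leave_one_out_ranks(default_model, m.CaseBase(cases=cohort50.cases[:1]))

    def test_spot_check_against_brute_force(self, default_model, cohort105):
        rankings = m.leave_one_out_ranks(default_model, cohort105)
        assert len(rankings) == 105 and all(len(r) == 104 for r in rankings)
        for i in (0, 17, 50, 88, 104):
            oracle = brute_force_ranking(default_model, cohort105, cohort105.cases[i])
            assert rankings[i].case_ids == tuple(cid for cid, _ in oracle)
            got = np.array(rankings[i].scores)
            exp = np.array([s for _, s in oracle])
            assert np.max(np.abs(got - exp)) < 1e-12

    def test_matrix_agrees_with_scalar_path(self, default_model, cohort50):
        S = m.similarity_matrix(default_model, cohort50)
        for i, j in [(0, 1), (2, 40), (13, 13), (49, 7)]:
            s = m.amalgamated_similarity(default_model,
                                         cohort50.cases[i].attributes,
                                         cohort50.cases[j].attributes)
            assert abs(S[i, j] - s) < 1e-12


class TestMeanCI:
    def test_degenerate_sample_zero_width(self):
        assert m.mean_ci([2, 2, 2]) == (2.0, 2.0, 2.0)

    def test_closed_form_t_interval(self):
        mean, lo, hi = m.mean_ci([1, 2, 3])
        exp_lo, exp_hi = stats.t.interval(0.95, df=2, loc=2.0,
                                          scale=stats.sem([1, 2, 3]))
        assert mean == 2.0
        assert lo == pytest.approx(exp_lo, abs=1e-12)
        assert hi == pytest.approx(exp_hi, abs=1e-12)

    def test_bootstrap_agrees_with_t(self):
        rng = np.random.default_rng(11)
        x = rng.normal(10, 2, size=200)
        _, lo_t, hi_t = m.mean_ci(x, method="t")
        _, lo_b, hi_b = m.mean_ci(x, method="bootstrap", n_boot=10_000,
                                  rng=np.random.default_rng(5))
        half_t, half_b = (hi_t - lo_t) / 2, (hi_b - lo_b) / 2
        assert abs(half_b - half_t) / half_t < 0.05

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            m.mean_ci([1.0])


class TestRankDifferenceCurve:
    def test_identical_patients_flat_zero(self, worked_example):
        model, query, _ = _full_sleep_example(worked_example)
        clones = m.CaseBase(cases=tuple(
            dataclasses.replace(query, case_id=f"c{i}") for i in range(4)
        ))
        rankings = m.leave_one_out_ranks(model, clones)
        curve = m.rank_difference_curve(rankings, clones, "omspq")
        for _, mean, lo, hi, n in curve.per_rank:
            assert mean == 0.0 and lo == 0.0 and hi == 0.0 and n == 4

    def test_nearest_neighbours_closer_than_farthest(self, default_model, cohort105):
        rankings = m.leave_one_out_ranks(default_model, cohort105)
        for instrument in ("omspq", "mskhq"):
            curve = m.rank_difference_curve(rankings, cohort105, instrument)
            assert curve.per_rank[0][1] < curve.per_rank[-1][1]

    def test_matches_flat_recomputation_oracle(self, default_model, cohort50):
        rankings = m.leave_one_out_ranks(default_model, cohort50)
        curve = m.rank_difference_curve(rankings, cohort50, "omspq")
        scores = {c.case_id: c.omspq for c in cohort50}
        for r, mean, _, _, n in curve.per_rank:
            vals = [abs(scores[res.query_id] - scores[res.ranking[r - 1][0]])
                    for res in rankings]
            assert n == len(vals) == 50
            assert mean == pytest.approx(np.mean(vals), abs=1e-12)

    def test_invariant_to_case_order(self, default_model, cohort50):
        curve1 = m.rank_difference_curve(
            m.leave_one_out_ranks(default_model, cohort50), cohort50, "omspq")
        rev = m.CaseBase(cases=tuple(reversed(cohort50.cases)))
        curve2 = m.rank_difference_curve(
            m.leave_one_out_ranks(default_model, rev), rev, "omspq")
        assert np.allclose(curve1.means, curve2.means)

    def test_rising_trend_under_latent_severity(self, default_model, cohort105):
        curve = m.rank_difference_curve(
            m.leave_one_out_ranks(default_model, cohort105), cohort105, "omspq")
        rho, p = m.rank_trend(curve)
        assert rho > 0 and p < 0.01

    def test_flat_under_zero_loadings(self, default_model):
        cb = m.generate_cohort(m.default_cohort_model(n=105, seed=2, loading_scale=0.0))
        curve = m.rank_difference_curve(
            m.leave_one_out_ranks(default_model, cb), cb, "omspq")
        r1, rlast = curve.per_rank[0], curve.per_rank[-1]
        se1 = (r1[3] - r1[1]) / stats.t.ppf(0.975, df=r1[4] - 1)
        se2 = (rlast[3] - rlast[1]) / stats.t.ppf(0.975, df=rlast[4] - 1)
        assert abs(r1[1] - rlast[1]) < 2 * np.hypot(se1, se2)


class TestCompareCaseBases:
    def test_identical_bases_identical_curves(self, default_model, cohort50):
        curves = m.compare_case_bases(default_model, cohort50, cohort50, k=10)
        assert curves["small"].per_rank == curves["large"].per_rank

    def test_nested_larger_base_finds_closer_neighbours(self, default_model):
        large = m.generate_cohort(m.default_cohort_model(n=486, seed=4))
        small = m.CaseBase(cases=large.cases[:105])
        curves = m.compare_case_bases(default_model, small, large, k=15)
        assert curves["large"].per_rank[0][1] >= curves["small"].per_rank[0][1]

    def test_two_case_bases_k1_equals_pairwise_similarity(self, default_model, cohort50):
        a = m.CaseBase(cases=cohort50.cases[:2])
        b = m.CaseBase(cases=cohort50.cases[2:4])
        curves = m.compare_case_bases(default_model, a, b, k=1)
        pair = m.amalgamated_similarity(default_model,
                                        a.cases[0].attributes, a.cases[1].attributes)
        assert curves["small"].per_rank[0][1] == pytest.approx(pair, abs=1e-12)
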