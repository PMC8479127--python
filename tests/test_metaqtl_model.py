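"""Known-variance Gaussian mixture fitting, criteria and K selection."""

import math

import numpy as np
import pytest

from ionmqtl.consensus_map import build_consensus
from ionmqtl.metaqtl_model import (
    CriteriaRow,
    criteria,
    em_fit,
    loglik,
    run_chromosome,
    select_K,
    summarize,
)
from ionmqtl.qtl_database import QTLRecord
from ionmqtl.qtl_projection import ProjectedQTL

from conftest import make_map


def projected(peak, sd, qid="q1", pop="p1", trait="Zn", lg="1"):
    half = 1.96 * sd
    rec = QTLRecord(qid, pop, trait, lg, peak, peak - half, peak + half)
    return ProjectedQTL(source=rec, peak_c=peak, ci_lo_c=peak - half,
                        ci_hi_c=peak + half, sd=sd)


class TestLoglik:
    def test_standard_normal_at_zero(self):
        assert loglik([0.0], [1.0], [0.0], [1.0]) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-10)

    def test_translation_invariance(self):
        x = [1.0, 3.5, 7.2]
        s = [0.8, 1.5, 2.0]
        mu, pi = [2.0, 6.0], [0.4, 0.6]
        base = loglik(x, s, mu, pi)
        shifted = loglik([v + 13.7 for v in x], s, [m + 13.7 for m in mu], pi)
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_matches_direct_summation_oracle(self):
        # positions and means kept in a narrow range so the naive density
        # summation of the oracle does not underflow
        rng = np.random.default_rng(21)
        for _ in range(20):
            n, K = int(rng.integers(2, 8)), int(rng.integers(1, 4))
            x = rng.uniform(0, 10, n)
            s = rng.uniform(1.0, 4, n)
            mu = rng.uniform(0, 10, K)
            pi = rng.dirichlet(np.ones(K))
            direct = sum(
                math.log(sum(
                    p * math.exp(-0.5 * ((xi - m) / si) ** 2) / (si * math.sqrt(2 * math.pi))
                    for m, p in zip(mu, pi)))
                for xi, si in zip(x, s))
            assert loglik(x, s, mu, pi) == pytest.approx(direct, abs=1e-12)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            loglik([0.0], [0.0], [0.0], [1.0])


class TestEMFit:
    def test_degenerate_equal_positions(self):
        model = em_fit([10.0] * 6, [1.0] * 6, K=1, seed=1)
        assert model.mu == pytest.approx([10.0])
        assert model.pi == pytest.approx([1.0])

    def test_two_well_separated_clusters_recovered(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([10 + rng.normal(0, 1, 5), 50 + rng.normal(0, 1, 5)])
        model = em_fit(x, np.ones(10), K=2, seed=4)
        assert abs(model.mu[0] - 10) < 0.5 * 3  # within a few sample-mean sds
        assert abs(model.mu[1] - 50) < 0.5 * 3
        # oracle: best 2-partition is the obvious split; component means are
        # the inverse-variance (here plain) means of each half
        assert model.mu[0] == pytest.approx(x[:5].mean(), abs=0.2)
        assert model.mu[1] == pytest.approx(x[5:].mean(), abs=0.2)

    def test_k1_is_inverse_variance_weighted_mean(self):
        x = np.array([3.0, 9.0, 15.0])
        s = np.array([0.5, 1.0, 2.0])
        model = em_fit(x, s, K=1, seed=2)
        w = 1 / s**2
        assert model.mu[0] == pytest.approx(np.sum(w * x) / np.sum(w), abs=1e-9)

    def test_k_exceeding_distinct_positions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            em_fit([5.0, 5.0], [1.0, 1.0], K=2)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 40, 12)
        s = rng.uniform(0.5, 3, 12)
        a = em_fit(x, s, K=3, seed=123)
        b = em_fit(x, s, K=3, seed=123)
        assert np.array_equal(a.mu, b.mu) and a.loglik == b.loglik

    def test_loglik_never_decreases_on_random_instances(self):
        # the EM loop asserts monotonicity at every iteration; fitting many
        # seeded random instances exercises that assertion
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(5, 25))
            x = rng.uniform(0, 100, n)
            s = rng.uniform(0.3, 4, n)
            K = int(rng.integers(1, min(6, n)))
            model = em_fit(x, s, K=K, seed=int(rng.integers(1000)))
            assert np.isfinite(model.loglik)


class TestCriteria:
    def test_worked_arithmetic(self):
        class Fake:
            K = 2
            loglik = -100.0
            classification_loglik = -100.0

        row = criteria(Fake(), n=20)
        assert row.p == 3
        assert row.aic == pytest.approx(206.0)
        assert row.aicc == pytest.approx(207.5)
        assert row.aic3 == pytest.approx(209.0)
        assert row.bic == pytest.approx(200 + 3 * math.log(20), abs=1e-9)

    def test_awe_penalty_exceeds_bic_penalty(self):
        # with p = 1 (K = 1), 2(3/2 + ln n) >= ln n for any n >= 1
        class Fake:
            K = 1
            loglik = -50.0
            classification_loglik = -50.0

        for n in (1, 2, 10, 1000):
            row = criteria(Fake(), n=n)
            assert row.awe >= row.bic

    def test_aicc_inadmissible_when_n_too_small(self):
        class Fake:
            K = 2
            loglik = -10.0
            classification_loglik = -10.0

        row = criteria(Fake(), n=4)  # n <= p + 1 = 4
        assert math.isnan(row.aicc)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            x = rng.uniform(0, 80, n)
            s = rng.uniform(0.5, 4, n)
            K = int(rng.integers(1, 5))
            model = em_fit(x, s, K=K, seed=int(rng.integers(1000)))
            row = criteria(model, n)
            p = 2 * K - 1
            L = model.loglik
            assert row.aic == pytest.approx(-2 * L + 2 * p, abs=1e-10)
            assert row.aicc == pytest.approx(-2 * L + 2 * p + 2 * p * (p + 1) / (n - p - 1), abs=1e-10)
            assert row.aic3 == pytest.approx(-2 * L + 3 * p, abs=1e-10)
            assert row.bic == pytest.approx(-2 * L + p * math.log(n), abs=1e-10)
            assert row.awe == pytest.approx(
                -2 * model.classification_loglik + 2 * p * (1.5 + math.log(n)), abs=1e-10)


def row(K, n=20, **vals):
    defaults = dict(p=2 * K - 1, loglik=0.0, aic=0.0, aicc=0.0, aic3=0.0, bic=0.0, awe=0.0)
    defaults.update(vals)
    return CriteriaRow(K=K, n=n, **defaults)


class TestSelectK:
    def test_three_of_five_wins(self):
        table = [row(1, aic=10, aicc=10, aic3=10, bic=1, awe=1),
                 row(2, aic=1, aicc=1, aic3=1, bic=10, awe=10)]
        assert select_K(table) == 2

    def test_single_candidate(self):
        assert select_K([row(1)]) == 1

    def test_fallback_tie_prefers_smaller_k(self):
        table = [row(1, aic=1, aicc=1, aic3=9, bic=9, awe=9),
                 row(2, aic=9, aicc=9, aic3=1, bic=1, awe=9),
                 row(3, aic=9, aicc=9, aic3=9, bic=9, awe=1)]
        assert select_K(table) == 1

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            select_K([])


class TestSummarize:
    def test_two_members_inverse_variance_pooling(self):
        members = [projected(10.0, 1.0, qid="q1", pop="p1"),
                   projected(14.0, 1.0, qid="q2", pop="p2")]
        model = em_fit([10.0, 14.0], [1.0, 1.0], K=1, seed=1)
        (mq,) = summarize(model, members)
        assert mq.position == pytest.approx(12.0)
        assert mq.ci_width == pytest.approx(2 * 1.96 / math.sqrt(2), abs=1e-9)
        assert mq.n_populations == 2
        assert mq.traits == {"Zn"}

    def test_single_member_keeps_member_ci(self):
        member = projected(10.0, 1.5, qid="q1")
        model = em_fit([10.0], [1.5], K=1, seed=1)
        (mq,) = summarize(model, [member])
        assert mq.ci_width == pytest.approx(member.ci_hi_c - member.ci_lo_c, abs=1e-9)

    def test_flanking_markers_outside_ci(self):
        cons = build_consensus([make_map("c", [("left", "1", 0.0), ("a", "1", 9.0),
                                               ("b", "1", 13.0), ("right", "1", 30.0)])])
        members = [projected(10.0, 0.5, qid="q1"), projected(11.0, 0.5, qid="q2")]
        model = em_fit([10.0, 11.0], [0.5, 0.5], K=1, seed=1)
        (mq,) = summarize(model, members, cons)
        assert mq.flanking_markers == ("a", "b")


class TestRunChromosome:
    def test_three_planted_clusters_selected(self):
        rng = np.random.default_rng(13)
        sd = 1.0
        means = [10.0, 35.0, 60.0]  # separated by 5x member sd x 5
        members = []
        for i in range(12):
            m = means[i % 3]
            members.append(projected(float(m + rng.normal(0, sd)), sd,
                                     qid=f"q{i}", pop=f"p{i % 4}"))
        mqtls, table = run_chromosome(members, seed=13)
        assert len(mqtls) == 3
        for mq, m in zip(mqtls, means):
            assert abs(mq.position - m) < 2.0

    def test_identical_positions_select_one(self):
        members = [projected(10.0, 1.0, qid=f"q{i}") for i in range(8)]
        mqtls, _ = run_chromosome(members, seed=1)
        assert len(mqtls) == 1

    def test_count_never_exceeds_kmax(self):
        rng = np.random.default_rng(19)
        members = [projected(float(rng.uniform(0, 100)), float(rng.uniform(0.5, 3)),
                             qid=f"q{i}") for i in range(15)]
        mqtls, table = run_chromosome(members, K_max=4, seed=19)
        assert len(mqtls) <= 4
        assert max(r.K for r in table) <= 4

    def test_permutation_invariant(self):
        rng = np.random.default_rng(23)
        members = [projected(float(rng.uniform(0, 80)), float(rng.uniform(0.5, 3)),
                             qid=f"q{i}") for i in range(14)]
        a, _ = run_chromosome(members, seed=5)
        shuffled = list(members)
        rng.shuffle(shuffled)
        b, _ = run_chromosome(shuffled, seed=5)
        assert [round(m.position, 9) for m in a] == [round(m.position, 9) for m in b]

    def test_too_few_qtls_rejected(self):
        with pytest.raises(ValueError):
            run_chromosome([projected(5.0, 1.0)], seed=1)

    def test_ci_shrinkage_with_equal_sds(self):
        # a component with m >= 2 equal-sd members has CI width ~ 1/sqrt(m)
        members = [projected(10.0 + 0.1 * i, 1.0, qid=f"q{i}") for i in range(5)]
        mqtls, _ = run_chromosome(members, seed=3)
        member_width = members[0].ci_hi_c - members[0].ci_lo_c
        assert all(m.ci_width <= member_width for m in mqtls)
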