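"""Event-level and skeleton simulators against the exact theory."""

import io

import numpy as np
import pytest
from scipy import stats

import yuleimm as ym
from yuleimm.params import BIParams, CountsOfCounts, Interval, TimePartition

from conftest import ALPHA, assert_within_se, chisquare_vs_esf, partition_frequencies


class TestEventLevel:
    def test_seed_determinism(self):
        p = BIParams(1.0, 1.0)
        a = ym.simulate_bi(p, 2.0, 123)
        b = ym.simulate_bi(p, 2.0, 123)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.to_csv(buf_a)
        b.to_csv(buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_negligible_immigration(self):
        pop = ym.simulate_bi(BIParams(1e-12, 1.0), 1.0, 0)
        assert pop.num_families == 0

    def test_event_csv_roundtrip(self):
        p = BIParams(1.0, 0.7)
        pop = ym.simulate_bi(p, 2.0, 5)
        buf = io.StringIO()
        pop.to_csv(buf)
        buf.seek(0)
        import pandas as pd
        back = ym.PopulationRealization.from_frame(pd.read_csv(buf), 2.0, p)
        assert back.popsize() == pop.popsize()
        assert back.num_families == pop.num_families

    def test_popsize_mean(self):
        """Mean Z(tau) over replicates matches theta*(e^tau - 1)."""
        p = BIParams(1.0, 1.0)
        rng = np.random.default_rng(21)
        z = np.array([ym.simulate_bi(p, 2.0, rng).popsize() for _ in range(20000)])
        assert_within_se(z.mean(), ym.popsize_mean(2.0, p), z.std() / np.sqrt(z.size))

    def test_popsize_negative_binomial_fit(self):
        """Z(tau) follows the negative-binomial population-size law."""
        p = BIParams(1.0, 1.0)
        rng = np.random.default_rng(22)
        z = np.array([ym.simulate_bi(p, 1.5, rng).popsize() for _ in range(20000)])
        kmax = int(z.max())
        probs = np.array([ym.popsize_pmf(k, 1.5, p) for k in range(kmax + 1)])
        # pool the tail so every expected cell is comfortably large
        cut = int(np.searchsorted(np.cumsum(probs), 0.995)) + 1
        obs = np.bincount(np.minimum(z, cut), minlength=cut + 1).astype(float)
        exp = np.append(probs[:cut], 1.0 - probs[:cut].sum()) * z.size
        pval = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
        assert pval > ALPHA

    def test_family_count_means_and_dispersion(self):
        """C_i(t) has the marked-Poisson mean and unit index of dispersion."""
        p = BIParams(1.0, 1.0)
        t = 1.5
        rng = np.random.default_rng(23)
        reps = 20000
        counts = np.zeros((reps, 3))
        for r in range(reps):
            cc = ym.simulate_bi(p, t, rng).counts_of_counts()
            for i in range(3):
                counts[r, i] = cc.counts[i] if i < len(cc.counts) else 0
        for i in range(3):
            exact = ym.family_count_mean(i + 1, t, p)
            assert_within_se(counts[:, i].mean(), exact,
                             counts[:, i].std(ddof=1) / np.sqrt(reps))
            dispersion = counts[:, i].var(ddof=1) / counts[:, i].mean()
            assert dispersion == pytest.approx(1.0, abs=0.05)

    def test_lam_zero_like_degenerate(self):
        # tiny birth rate: families essentially never grow, S_i = arrivals
        p = BIParams(2.0, 1e-9)
        pop = ym.simulate_bi(p, 3.0, 9)
        part = TimePartition([0, 1.0, 2.0, 3.0])
        S = ym.count_observed(pop, part).counts
        arrivals = np.array([sum(1 for f in pop.families
                                 if lo <= f.arrival < hi)
                             for lo, hi in zip(part.points[:-1], part.points[1:])])
        assert np.array_equal(S, arrivals)


class TestCountObserved:
    def test_empty_population(self):
        pop = ym.PopulationRealization((), 2.0, BIParams(1.0))
        S = ym.count_observed(pop, TimePartition([0, 1, 2]))
        assert np.array_equal(S.counts, [0, 0])

    def test_hand_trace(self):
        fam = ym.FamilyTrajectory(0.5, np.array([0.7, 1.3]))
        pop = ym.PopulationRealization((fam,), 2.0, BIParams(1.0))
        S = ym.count_observed(pop, TimePartition([0, 1, 2]))
        assert np.array_equal(S.counts, [1, 1])

    def test_partition_beyond_horizon_rejected(self):
        pop = ym.simulate_bi(BIParams(1.0), 1.0, 0)
        with pytest.raises(ValueError):
            ym.count_observed(pop, TimePartition([0, 2.0]))

    def test_single_window_mean_theta_b(self):
        """S(0, b) is Poisson with mean theta*b (event-level route)."""
        p = BIParams(1.0, 1.0)
        rng = np.random.default_rng(31)
        part = TimePartition([0, 1.5])
        s = np.array([ym.count_observed(ym.simulate_bi(p, 1.5, rng), part).counts[0]
                      for _ in range(20000)])
        assert_within_se(s.mean(), 1.5, s.std(ddof=1) / np.sqrt(s.size))

    def test_sample_variance_of_constant_counts(self):
        assert ym.ObservedCounts(np.array([3, 3, 3])).sample_variance() == 0.0


class TestSkeletonSampler:
    def test_matches_event_level_counts(self):
        """Window-skeleton and event-level simulators agree in mean."""
        p = BIParams(1.0, 0.8)
        part = TimePartition([0, 1.0, 2.0])
        rng = np.random.default_rng(41)
        ev = np.array([ym.count_observed(ym.simulate_bi(p, 2.0, rng), part).counts
                       for _ in range(20000)])
        sk = ym.sample_window_counts(p, part, 20000, 42)
        for i in range(2):
            se = np.sqrt(ev[:, i].var(ddof=1) / ev.shape[0]
                         + sk[:, i].var(ddof=1) / sk.shape[0])
            assert_within_se(sk[:, i].mean(), ev[:, i].mean(), se)

    def test_window_means_match_corollary(self):
        """E S_i = theta*log(e^{t_i} - e^{t_{i-1}} + 1) per window."""
        p = BIParams(0.8, 1.3)
        part = TimePartition([0, 0.5, 1.2, 2.0])
        S = ym.sample_window_counts(p, part, 100000, 43)
        for i in range(3):
            exact = ym.mean_observed(part.points[i], part.points[i + 1], p)
            assert_within_se(S[:, i].mean(), exact,
                             S[:, i].std(ddof=1) / np.sqrt(S.shape[0]))

    def test_covariance_matches_corollary(self):
        """Empirical Cov(S_i, S_j) matches the shared-component formula."""
        p = BIParams(1.0, 1.0)
        part = TimePartition([0, 1.0, 2.0])
        S = ym.sample_window_counts(p, part, 100000, 44)
        prod = (S[:, 0] - S[:, 0].mean()) * (S[:, 1] - S[:, 1].mean())
        exact = ym.cov_observed(Interval(0, 1), Interval(1, 2), p)
        assert_within_se(prod.mean(), exact, prod.std(ddof=1) / np.sqrt(S.shape[0]))


@pytest.fixture(scope="module")
def table():
    p = BIParams(1.0, 1.0)
    # segments cut at every endpoint used by the marked-Poisson MC checks
    rep, x, seg0, grew = ym.sample_family_table(p, [0, 1.0, 2.0, 2.5, 3.0],
                                                100000, 51)
    return p, rep, x, seg0, grew, 100000


class TestMarkedPoissonCountsMC:
    """Monte-Carlo means of the (un)observable family counts, 3 SE bands."""

    def test_lemma_unobservable(self, table):
        """V_J(I): arrivals in J=(0,1) with no birth in I=(1,2)."""
        p, rep, x, seg0, grew, reps = table
        v = (seg0 == 0) & ~grew[:, 1]
        per_rep = np.bincount(rep[v], minlength=reps)
        exact = ym.mean_unobservable(Interval(0, 1), Interval(1, 2), p)
        assert_within_se(per_rep.mean(), exact, per_rep.std(ddof=1) / np.sqrt(reps))

    def test_lemma_unobservable_two(self, table):
        """V_J(I1, I2): arrivals before 1 with no birth in (1,2) nor (2.5,3)."""
        p, rep, x, seg0, grew, reps = table
        v = (seg0 == 0) & ~grew[:, 1] & ~grew[:, 3]
        per_rep = np.bincount(rep[v], minlength=reps)
        exact = ym.mean_unobservable_two(1.0, Interval(1, 2), Interval(2.5, 3), p)
        assert_within_se(per_rep.mean(), exact, per_rep.std(ddof=1) / np.sqrt(reps))

    def test_lemma_observable(self, table):
        """U_J(I): arrivals in J=(0,1) with >= 1 birth in I=(1,2)."""
        p, rep, x, seg0, grew, reps = table
        u = (seg0 == 0) & grew[:, 1]
        per_rep = np.bincount(rep[u], minlength=reps)
        exact = ym.mean_observable(Interval(0, 1), Interval(1, 2), p)
        assert_within_se(per_rep.mean(), exact, per_rep.std(ddof=1) / np.sqrt(reps))

    def test_theorem_decomposition_means_and_independence(self, table):
        """K, T(I1\\I2), T(I2\\I1) have the stated means and zero correlation."""
        p, rep, x, seg0, grew, reps = table
        I1, I2 = Interval(0, 1), Interval(1, 2)
        obs1 = (seg0 == 0) | grew[:, 0]       # any event in (0,1)
        obs2 = (seg0 == 1) | grew[:, 1]       # any event in (1,2)
        k_mask = obs1 & obs2
        t1_mask = obs1 & ~obs2
        t2_mask = obs2 & ~obs1
        ek, et1, et2 = ym.decomposition_means(I1, I2, p)
        triples = []
        for mask, exact in ((k_mask, ek), (t1_mask, et1), (t2_mask, et2)):
            per_rep = np.bincount(rep[mask], minlength=reps)
            assert_within_se(per_rep.mean(), exact,
                             per_rep.std(ddof=1) / np.sqrt(reps))
            triples.append(per_rep)
        # pairwise correlations compatible with independence
        for a in range(3):
            for b in range(a + 1, 3):
                r = np.corrcoef(triples[a], triples[b])[0, 1]
                assert abs(r) < 3.0 / np.sqrt(reps)


class TestEmpiricalESV:
    def test_study_grid_cell(self):
        """Monte-Carlo E V_p within 3 SE of the exact value (both kinds)."""
        p = BIParams(0.25, 0.1)
        emp, se = ym.empirical_esv(p, TimePartition.equal(25, 10, 0.1), 5000, 61)
        assert_within_se(emp, ym.equal_intervals_esv(25, 10, p), se)
        emp, se = ym.empirical_esv(p, TimePartition.log_equal(25, 10, 0.1), 5000, 62)
        assert_within_se(emp, ym.log_intervals_esv(25, 10, p), se)


class TestCRP:
    def test_single_arrival(self):
        assert ym.simulate_crp(1, 1.0, 0).counts == (1,)

    def test_two_arrivals_probability(self):
        sizes = ym.sample_crp_sizes(2, 1.0, 100000, 71)
        phat = np.mean(sizes[:, 0] == 1)
        se = np.sqrt(0.25 / sizes.shape[0])
        assert_within_se(phat, 0.5, se)

    def test_goodness_of_fit_to_esf(self):
        """CRP partitions at n=6, theta=0.8 follow the ESF."""
        sizes = ym.sample_crp_sizes(6, 0.8, 100000, 72)
        assert chisquare_vs_esf(sizes, 6, 0.8) > ALPHA

    def test_domain(self):
        with pytest.raises(ValueError):
            ym.simulate_crp(0, 1.0, 0)


class TestJumpChainEmbedding:
    def test_first_individual(self):
        pop = ym.simulate_bi(BIParams(1.0), 1.5, 3)
        if pop.popsize() >= 1:
            assert ym.jump_counts(pop, 1).counts == (1,)

    def test_too_few_individuals(self):
        fam = ym.FamilyTrajectory(0.5, np.array([0.7]))
        pop = ym.PopulationRealization((fam,), 1.0, BIParams(1.0))
        with pytest.raises(ValueError):
            ym.jump_counts(pop, 3)

    def test_batch_matches_event_level(self):
        """The batch first-n sampler agrees with simulate_bi + jump_counts."""
        p = BIParams(1.0, 1.0)
        rng = np.random.default_rng(81)
        n, reps = 4, 4000
        rows = []
        while len(rows) < reps:
            pop = ym.simulate_bi(p, 2.2, rng)
            try:
                cc = ym.jump_counts(pop, n)
            except ValueError:
                continue
            rows.append(tuple(cc.sizes() + [0] * (n - cc.num_families)))
        batch = ym.sample_jump_counts(p, n, reps, 82)
        f_ev = partition_frequencies(np.array(rows))
        f_ba = partition_frequencies(batch)
        keys = sorted(set(f_ev) | set(f_ba))
        obs = np.array([[f_ev.get(k, 0) for k in keys],
                        [f_ba.get(k, 0) for k in keys]], dtype=float)
        assert stats.chi2_contingency(obs).pvalue > ALPHA

    def test_jump_counts_distributed_as_crp(self):
        """First-n family counts of the BI process match the CRP law."""
        p = BIParams(1.0, 1.0)
        jumps = ym.sample_jump_counts(p, 5, 100000, 83)
        assert chisquare_vs_esf(jumps, 5, 1.0) > ALPHA

    def test_embedding_invariant_to_horizon(self):
        """The first-n law does not depend on the simulation horizon."""
        p = BIParams(1.0, 1.0)
        a = ym.sample_jump_counts(p, 4, 40000, 84, horizon=2.0)
        b = ym.sample_jump_counts(p, 4, 40000, 85, horizon=4.0)
        fa, fb = partition_frequencies(a), partition_frequencies(b)
        keys = sorted(set(fa) | set(fb))
        obs = np.array([[fa.get(k, 0) for k in keys],
                        [fb.get(k, 0) for k in keys]], dtype=float)
        assert stats.chi2_contingency(obs).pvalue > ALPHA

    def test_conditional_law_is_esf(self):
        """C(t) given Z(t) = n follows the ESF at the matched time."""
        sizes = ym.sample_conditional_counts(1.0, 5, 50000, 86)
        assert chisquare_vs_esf(sizes, 5, 1.0) > ALPHA
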