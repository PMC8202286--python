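import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, poisson

import pvcausal as pv
from pvcausal.disproportionality import (
    ContingencyTable,
    EBGMPrior,
    ebgm_fit_counts,
    ebgm_score,
    prr,
    ror,
)

REFERENCE = ContingencyTable(a=10, b=90, c=10, d=890)


class TestContingency:
    def test_four_singleton_reports(self, toy_schema):
        reports = [
            pv.CaseReport("r1", {"gender": {"male"}, "drug": {"APAP"}, "outcomes": {"death"}}),
            pv.CaseReport("r2", {"gender": {"male"}, "drug": {"APAP"}, "outcomes": {"recovered"}}),
            pv.CaseReport("r3", {"gender": {"male"}, "drug": {"tramadol"}, "outcomes": {"death"}}),
            pv.CaseReport("r4", {"gender": {"male"}, "drug": {"tramadol"}, "outcomes": {"recovered"}}),
        ]
        t = pv.build_contingency(reports, "APAP", "drug", toy_schema)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_margins_match_do_calculus_partition(self, planted_study):
        schema, reports = planted_study["schema"], planted_study["reports"]
        probs = planted_study["probs"]
        part = pv.partition_by_term(reports, probs, "gender", "female", schema)
        t = pv.build_contingency(
            [r for r in reports if r.report_id in probs], "female", "gender", schema
        )
        assert t.a + t.b == len(part.l1_ids)
        assert t.c + t.d == len(part.l2_ids)

    def test_absent_term_gives_empty_first_row(self, toy_schema):
        reports = [
            pv.CaseReport("r1", {"gender": {"male"}, "drug": {"tramadol"}, "outcomes": {"death"}}),
        ]
        t = pv.build_contingency(reports, "APAP", "drug", toy_schema)
        assert t.a == 0 and t.b == 0 and t.c == 1

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestPRR:
    def test_reference_closed_form(self):
        s = prr(REFERENCE)
        assert s.score == pytest.approx(9.0)
        assert s.chi2 == pytest.approx(36.28, abs=0.01)
        assert s.is_signal

    def test_balanced_rates_give_one(self):
        s = prr(ContingencyTable(10, 90, 10, 90))
        assert s.score == pytest.approx(1.0) and not s.is_signal

    def test_cooccurrence_gate(self):
        # PRR and chi2 clear their cut-offs but a < 3 blocks the signal
        t = ContingencyTable(2, 2, 10, 200)
        s = prr(t)
        assert s.score >= 2 and s.chi2 >= 4 and not s.is_signal

    def test_zero_comparator_sentinel(self):
        s = prr(ContingencyTable(5, 5, 0, 100))
        assert s.score == math.inf

    def test_point_estimate_scale_invariant(self):
        s1 = prr(ContingencyTable(4, 16, 10, 170))
        s2 = prr(ContingencyTable(40, 160, 100, 1700))
        assert s1.score == pytest.approx(s2.score)


class TestROR:
    def test_reference_closed_form(self):
        s = ror(REFERENCE)
        assert s.score == pytest.approx(9.889, abs=0.001)
        assert s.ci_low == pytest.approx(4.008, abs=0.005)
        assert s.is_signal

    def test_uniform_table_gives_one(self):
        s = ror(ContingencyTable(25, 25, 25, 25))
        assert s.score == pytest.approx(1.0) and not s.is_signal

    def test_interval_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = ContingencyTable(*(int(x) for x in rng.integers(0, 400, 4)))
            s = ror(t)
            ci_high = math.exp(
                2 * math.log(s.score) - math.log(s.ci_low)
            )  # symmetric on the log scale
            assert s.ci_low < s.score < ci_high or s.score == pytest.approx(s.ci_low)

    def test_zero_cell_haldane_correction(self):
        s = ror(ContingencyTable(5, 0, 10, 100))
        assert math.isfinite(s.score) and s.score > 0


class TestEBGM:
    PRIOR = EBGMPrior(alpha1=1.2, beta1=1.1, alpha2=3.0, beta2=0.5, p=0.4)

    def test_zero_count_shrinks_below_one(self):
        # a = 0 with a prior centered near 1 must land below the null
        t = ContingencyTable(0, 50, 50, 400)
        s = ebgm_score(t, self.PRIOR)
        assert s.score < 1.0 and not s.is_signal

    def test_large_count_limit_approaches_relative_rate(self):
        t = ContingencyTable(5000, 5000, 100, 99900)
        s = ebgm_score(t, self.PRIOR)
        rel = t.a / t.expected
        assert s.score == pytest.approx(rel, rel=0.10)

    def test_posterior_matches_numerical_integration(self):
        # independent route: integrate prior x Poisson likelihood on a grid,
        # never using gamma-posterior conjugacy
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = ContingencyTable(
                int(rng.integers(0, 150)), int(rng.integers(1, 400)),
                int(rng.integers(1, 400)), int(rng.integers(1, 1500)),
            )
            s = ebgm_score(t, self.PRIOR)
            E = max(t.expected, 1e-10)
            lam = np.linspace(1e-8, max(30.0, 6 * (t.a + 5) / E), 400_001)
            prior_pdf = self.PRIOR.p * gamma_dist.pdf(
                lam, self.PRIOR.alpha1, scale=1 / self.PRIOR.beta1
            ) + (1 - self.PRIOR.p) * gamma_dist.pdf(
                lam, self.PRIOR.alpha2, scale=1 / self.PRIOR.beta2
            )
            post = prior_pdf * poisson.pmf(t.a, lam * E)
            w = post / post.sum()
            ebgm_num = math.exp(float(np.sum(w[1:] * np.log(lam[1:]))))
            eb05_num = float(lam[np.searchsorted(np.cumsum(w), 0.05)])
            assert s.score == pytest.approx(ebgm_num, abs=1e-4, rel=1e-4)
            assert s.eb05 == pytest.approx(eb05_num, abs=1e-4, rel=1e-3)

    def test_shrinkage_decreases_with_information(self):
        # same relative rate a/E = 4, more counts -> estimate further from 1
        small = ebgm_score(ContingencyTable(4, 96, 100, 9900), self.PRIOR)
        large = ebgm_score(ContingencyTable(40, 960, 1000, 99000), self.PRIOR)
        assert abs(large.score - 1) > abs(small.score - 1)

    def test_single_gamma_hyperparameter_recovery(self):
        rng = np.random.default_rng(12)
        n, true_shape, true_rate = 5000, 2.0, 1.5
        E = rng.uniform(2, 60, n)
        lam = rng.gamma(true_shape, 1 / true_rate, n)
        a = rng.poisson(lam * E).astype(float)
        prior = ebgm_fit_counts(a, E, seed=0)
        dominant = max(
            [(prior.p, prior.alpha1, prior.beta1), (1 - prior.p, prior.alpha2, prior.beta2)]
        )
        _, shape, rate = dominant
        assert shape == pytest.approx(true_shape, rel=0.20)
        assert rate == pytest.approx(true_rate, rel=0.20)

    def test_mixture_weight_recovery_with_separated_clusters(self):
        rng = np.random.default_rng(4)
        n = 5000
        E = rng.uniform(2, 60, n)
        low = rng.gamma(50, 0.01, n)   # tight cluster at lambda ~ 0.5
        high = rng.gamma(50, 0.1, n)   # tight cluster at lambda ~ 5
        pick = rng.random(n) < 0.3
        a = rng.poisson(np.where(pick, low, high) * E).astype(float)
        prior = ebgm_fit_counts(a, E, seed=0)
        w_low = prior.p if prior.alpha1 / prior.beta1 < prior.alpha2 / prior.beta2 else 1 - prior.p
        assert w_low == pytest.approx(0.3, abs=0.1)

    def test_self_consistent_tables_concentrate_near_one(self):
        # every table observes exactly its expectation: the fitted prior must
        # put its mass near lambda = 1
        rng = np.random.default_rng(8)
        tables = []
        for _ in range(200):
            ab = int(rng.integers(50, 500))
            ac_frac = rng.uniform(0.2, 0.8)
            n = int(ab / 0.1)
            ac = int(ac_frac * n)
            a = max(1, round(ab * ac / n))
            tables.append(ContingencyTable(a, ab - a, ac - a, n - ab - ac + a))
        prior = pv.ebgm_fit(tables, seed=0)
        weight, shape, rate = max(
            [(prior.p, prior.alpha1, prior.beta1),
             (1 - prior.p, prior.alpha2, prior.beta2)]
        )
        assert weight > 0.9  # essentially all mass in one component ...
        assert shape / rate == pytest.approx(1.0, abs=0.05)  # ... centered at 1
        assert math.sqrt(shape) / rate < 0.1  # ... and tight (sd of lambda)

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValueError):
            pv.ebgm_fit([REFERENCE] * 5)


class TestCompareMethods:
    UNIVERSE = ["a", "b", "c", "d"]

    @staticmethod
    def _sig(names, universe=None):
        universe = universe or TestCompareMethods.UNIVERSE
        return {t: t in names for t in universe}

    def test_identical_sets(self):
        report = pv.compare_methods(
            ["a", "b"], self._sig({"a", "b"}), self._sig({"a", "b"}), self._sig({"a", "b"})
        )
        assert report["four_way_intersection"] == ["a", "b"]
        assert report["counts"] == {"do_calculus": 2, "PRR": 2, "ROR": 2, "EBGM": 2}

    def test_disjoint_sets(self):
        report = pv.compare_methods(
            ["a"], self._sig({"b"}), self._sig({"c"}), self._sig({"d"})
        )
        assert report["four_way_intersection"] == []
        assert report["pairwise_intersections"]["do_calculus & PRR"] == []

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            pv.compare_methods(
                ["a"], self._sig({"a"}), self._sig({"a"}, universe=["a", "x"]),
                self._sig({"a"}),
            )

    def test_region_bookkeeping(self):
        report = pv.compare_methods(
            ["a", "b", "c"], self._sig({"a", "b"}), self._sig({"b", "d"}), self._sig(set())
        )
        for m, n in report["counts"].items():
            assert n == len(report["sets"][m])
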