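import numpy as np
import pytest
from scipy.stats import truncnorm

import omtrace as ot
from omtrace.data_model import SourceSummary, ValidationError, summarize_group
from omtrace.signature_selection import CompositeSignature
from omtrace.uncertainty import (
    MonteCarloConfig,
    MonteCarloError,
    PosteriorDistribution,
    catchment_summary,
    combine_signatures,
    run_monte_carlo,
    sample_deviates,
    weighted_mean_R,
)


def make_summary(median, qn, vmin, vmax, category="farmyard_manure", cv=None):
    tracers = tuple(median)
    return SourceSummary(
        tracers=tracers,
        median=median,
        qn=qn,
        vmin=vmin,
        vmax=vmax,
        n_samples=8,
        category=category,
        cv=cv or {t: 0.1 for t in tracers},
    )


def uniform_signature(tracers, method="KW-H"):
    return CompositeSignature(
        method=method,
        tracers=tuple(tracers),
        classification_pct={t: 90.0 for t in tracers},
        tdw={t: 1.0 for t in tracers},
        overall_classification_pct=100.0,
    )


class TestSampleDeviates:
    def test_zero_qn_gives_constant_column(self):
        summ = make_summary({"x": 5.0}, {"x": 0.0}, {"x": 5.0}, {"x": 5.0})
        dev = sample_deviates(summ, 50, rng=1)
        assert np.all(dev == 5.0)

    def test_each_stratum_used_exactly_once(self):
        summ = make_summary({"x": 5.0}, {"x": 1.0}, {"x": 2.0}, {"x": 8.0})
        n = 40
        dev = sample_deviates(summ, n, rng=2)[:, 0]
        a, b = (2.0 - 5.0) / 1.0, (8.0 - 5.0) / 1.0
        u = truncnorm.cdf(dev, a, b, loc=5.0, scale=1.0)
        strata = np.floor(u * n).astype(int)
        assert sorted(strata) == list(range(n))

    def test_moments_match_truncated_normal(self):
        med, qn, lo, hi = 10.0, 2.0, 5.0, 16.0
        summ = make_summary({"x": med}, {"x": qn}, {"x": lo}, {"x": hi})
        dev = sample_deviates(summ, 10_000, rng=3)[:, 0]
        a, b = (lo - med) / qn, (hi - med) / qn
        expected = truncnorm.stats(a, b, loc=med, scale=qn, moments="mv")
        assert dev.mean() == pytest.approx(expected[0], rel=0.01)
        assert dev.std() == pytest.approx(np.sqrt(expected[1]), rel=0.02)
        assert dev.min() >= lo and dev.max() <= hi

    def test_independent_tracer_stratification(self):
        summ = make_summary(
            {"x": 0.0, "y": 0.0},
            {"x": 1.0, "y": 1.0},
            {"x": -4.0, "y": -4.0},
            {"x": 4.0, "y": 4.0},
        )
        dev = sample_deviates(summ, 200, rng=4)
        r = np.corrcoef(dev.T)[0, 1]
        assert abs(r) < 0.2


class TestWeightedMeanR:
    def dist(self, freq, mids=None):
        freq = np.asarray(freq, float)
        mids = (
            np.asarray(mids, float)
            if mids is not None
            else (np.arange(len(freq)) + 0.5) / len(freq)
        )
        return PosteriorDistribution(
            category="farmyard_manure",
            bin_mid=mids,
            frequency=freq,
            r_weighted_mean=float(mids @ freq),
            full_range=(float(mids.min()), float(mids.max())),
        )

    def test_point_mass(self):
        d = self.dist([0.0, 1.0], mids=[0.25, 0.5])
        assert weighted_mean_R(d) == 0.5

    def test_uniform_is_half(self):
        d = self.dist(np.full(100, 0.01))
        assert weighted_mean_R(d) == pytest.approx(0.5)

    def test_matches_dot_product(self):
        rng = np.random.default_rng(5)
        f = rng.dirichlet(np.ones(20))
        d = self.dist(f)
        assert weighted_mean_R(d) == pytest.approx(float(d.bin_mid @ f))

    def test_unnormalised_rejected(self):
        with pytest.raises(ValidationError):
            self.dist([0.4, 0.4])


class TestCombineSignatures:
    def test_single_signature_identity(self):
        r = {"farmyard_manure": 0.37, "road_verge": 0.63}
        assert combine_signatures([(r, 0.9, 100.0)]) == {
            "farmyard_manure": 0.37,
            "road_verge": 0.63,
        }

    def test_combined_bounded_by_extremes(self):
        rng = np.random.default_rng(6)
        results = []
        for _ in range(5):
            p = rng.dirichlet(np.ones(4))
            r = dict(zip(ot.DEFAULT_CATEGORIES, p))
            results.append((r, rng.uniform(0.86, 0.99), rng.uniform(90, 100)))
        combined = combine_signatures(results)
        for cat in ot.DEFAULT_CATEGORIES:
            values = [r[cat] for r, _g, _c in results]
            assert min(values) - 0.005 <= combined[cat] <= max(values) + 0.005

    def test_weighting_pulls_toward_high_alpha(self):
        low = ({"a": 0.0, "b": 1.0}, 0.86, 50.0)
        high = ({"a": 1.0, "b": 0.0}, 0.99, 100.0)
        combined = combine_signatures([low, high])
        assert combined["a"] > 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            combine_signatures([])


class TestCatchmentSummary:
    def test_identical_subcatchments(self):
        per_sub = {s: {"farmyard_manure": 0.4} for s in "abc"}
        assert catchment_summary(per_sub) == {"farmyard_manure": 40}

    def test_mean_across_subcatchments(self):
        per_sub = {
            "a": {"farmyard_manure": 0.2},
            "b": {"farmyard_manure": 0.6},
        }
        assert catchment_summary(per_sub) == {"farmyard_manure": 40}


class TestRunMonteCarlo:
    def well_posed(self, qn_zero=False):
        rng = np.random.default_rng(7)
        tracers = tuple(f"t{i}" for i in range(5))
        cats = ot.DEFAULT_CATEGORIES
        s = rng.uniform(1, 10, size=(4, 5))
        p_true = np.array([0.5, 0.3, 0.15, 0.05])
        c = p_true @ s
        scale = 0.0 if qn_zero else 0.03
        sources = []
        for k, cat in enumerate(cats):
            sources.append(
                make_summary(
                    {t: s[k, j] for j, t in enumerate(tracers)},
                    {t: scale * s[k, j] for j, t in enumerate(tracers)},
                    {t: s[k, j] * 0.85 for j, t in enumerate(tracers)},
                    {t: s[k, j] * 1.15 for j, t in enumerate(tracers)},
                    category=cat,
                )
            )
        sediment = ot.SedimentSummary(
            tracers=tracers,
            median={t: c[j] for j, t in enumerate(tracers)},
            qn={t: scale * c[j] for j, t in enumerate(tracers)},
            vmin={t: c[j] * 0.9 for j, t in enumerate(tracers)},
            vmax={t: c[j] * 1.1 for j, t in enumerate(tracers)},
            n_samples=3,
        )
        return uniform_signature(tracers), sources, sediment, p_true

    def test_degenerate_summaries_give_point_mass(self):
        sig, sources, sediment, p_true = self.well_posed(qn_zero=True)
        cfg = MonteCarloConfig(n_accept=50, gof_threshold=0.85, seed=1)
        mc = run_monte_carlo(sig, sources, sediment, cfg)
        prob = ot.MixingProblem(
            tracers=sig.tracers,
            categories=mc.categories,
            c=np.array([sediment.median[t] for t in sig.tracers]),
            s=np.array([[s.median[t] for t in sig.tracers] for s in sources]),
            sv=np.array([[1 / s.cv[t] for t in sig.tracers] for s in sources]),
            w=np.ones(len(sig.tracers)),
        )
        det = ot.solve(prob)
        for k, cat in enumerate(mc.categories):
            dist = mc.posteriors[cat]
            assert np.count_nonzero(dist.frequency) == 1
            assert abs(dist.r_weighted_mean - det.p[k]) <= 1.0 / cfg.n_bins

    def test_accepted_solutions_respect_threshold(self):
        sig, sources, sediment, _ = self.well_posed()
        cfg = MonteCarloConfig(n_accept=100, gof_threshold=0.9, seed=2)
        mc = run_monte_carlo(sig, sources, sediment, cfg)
        assert np.all(mc.accepted_gof > 0.9)
        for cat in mc.categories:
            dist = mc.posteriors[cat]
            assert dist.frequency.sum() == pytest.approx(1.0, abs=1e-12)
            lo, hi = dist.full_range
            assert lo - 0.005 <= dist.r_weighted_mean <= hi + 0.005

    def test_zero_threshold_accepts_everything(self):
        sig, sources, sediment, _ = self.well_posed()
        cfg = MonteCarloConfig(n_accept=60, gof_threshold=0.0, seed=3)
        mc = run_monte_carlo(sig, sources, sediment, cfg)
        assert mc.n_drawn == 60

    def test_parameter_recovery_moderate_noise(self):
        sig, sources, sediment, p_true = self.well_posed()
        cfg = MonteCarloConfig(n_accept=300, gof_threshold=0.85, seed=4)
        mc = run_monte_carlo(sig, sources, sediment, cfg)
        for k, cat in enumerate(mc.categories):
            assert abs(mc.posteriors[cat].r_weighted_mean - p_true[k]) <= 0.1

    def test_fixed_seed_bit_identical(self):
        sig, sources, sediment, _ = self.well_posed()
        cfg = MonteCarloConfig(n_accept=80, gof_threshold=0.85, seed=5)
        a = run_monte_carlo(sig, sources, sediment, cfg)
        b = run_monte_carlo(sig, sources, sediment, cfg)
        assert np.array_equal(a.accepted_p, b.accepted_p)
        assert np.array_equal(a.accepted_gof, b.accepted_gof)

    def test_impossible_acceptance_raises(self):
        sig, sources, sediment, _ = self.well_posed()
        bad_sediment = ot.SedimentSummary(
            tracers=sediment.tracers,
            median={t: sediment.median[t] * 10 for t in sediment.tracers},
            qn=sediment.qn,
            vmin={t: sediment.vmin[t] * 10 for t in sediment.tracers},
            vmax={t: sediment.vmax[t] * 10 for t in sediment.tracers},
            n_samples=3,
        )
        cfg = MonteCarloConfig(n_accept=10, gof_threshold=0.99, max_draws=50, seed=6)
        with pytest.raises(MonteCarloError, match="best GOF"):
            run_monte_carlo(sig, sources, bad_sediment, cfg)
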