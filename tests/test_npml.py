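"""Unit tests for grid initialization, likelihoods, EM weights, posteriors,
diagnostics and covariate screening."""

import math

import numpy as np
import pytest
from scipy import stats

import pkadherence as pa
from pkadherence.npml import (
    DEFAULT_RANGES,
    FitResult,
    NPDistribution,
    SubjectPosterior,
    SubjectRecord,
    weighted_median,
)
from pkadherence.pk import ASSAY_ERROR, DoseEvent, Observation, PKParams

from oracles import bruteforce_two_point_weights

EM = ASSAY_ERROR["ATR_ATRL"]


def make_subject(sid="s1", obs=((2.0, 50.0), (4.0, 40.0), (6.0, 30.0)),
                 dose=20.0, c_ini=0.0, covariates=None):
    return SubjectRecord(
        id=sid,
        events=(DoseEvent(0.0, dose),),
        observations=tuple(Observation(t, c) for t, c in obs),
        c_ini=c_ini,
        covariates=covariates or {},
    )


class TestInitGrid:
    def test_single_point_is_midpoint(self):
        (p,) = pa.init_grid(DEFAULT_RANGES, 1, seed=0)
        assert p.ka == pytest.approx((0.01 + 9.0) / 2)
        assert p.ke == pytest.approx((0.01 + 0.6) / 2)
        assert p.v == pytest.approx((5.0 + 100.0) / 2)

    def test_contained_and_deterministic(self):
        g1 = pa.init_grid(DEFAULT_RANGES, 40, seed=3)
        g2 = pa.init_grid(DEFAULT_RANGES, 40, seed=3)
        assert [(p.ka, p.ke, p.v) for p in g1] == [(p.ka, p.ke, p.v) for p in g2]
        for p in g1:
            assert 0.01 <= p.ka <= 9.0 and 0.01 <= p.ke <= 0.6 and 5.0 <= p.v <= 100.0

    def test_corners_included(self):
        pts = {(p.ka, p.ke, p.v) for p in pa.init_grid(DEFAULT_RANGES, 12, seed=0)}
        for ka in (0.01, 9.0):
            for ke in (0.01, 0.6):
                for v in (5.0, 100.0):
                    assert (ka, ke, v) in pts

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            pa.init_grid({"ka": (2.0, 1.0), "ke": (0.01, 0.6), "v": (5, 100)}, 5, 0)


class TestSubjectLoglik:
    def test_exact_prediction_closed_form(self):
        point = PKParams(ka=1.74, ke=0.135, v=44.75)
        t = 4.0
        pred = pa.conc_profile(point, [DoseEvent(0.0, 20.0)], t)
        s = make_subject(obs=((t, pred),))
        sd = EM.total_sd(pred)
        assert pa.subject_loglik(s, point, EM) == pytest.approx(
            math.log(1.0 / (sd * math.sqrt(2 * math.pi)))
        )

    def test_additive_over_observations(self):
        point = PKParams(ka=1.2, ke=0.2, v=30.0)
        s12 = make_subject(obs=((2.0, 40.0), (6.0, 25.0)))
        s1 = make_subject(obs=((2.0, 40.0),))
        s2 = make_subject(obs=((6.0, 25.0),))
        assert pa.subject_loglik(s12, point, EM) == pytest.approx(
            pa.subject_loglik(s1, point, EM) + pa.subject_loglik(s2, point, EM)
        )

    def test_matches_direct_density_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            point = PKParams(
                ka=rng.uniform(0.1, 5), ke=rng.uniform(0.05, 0.5), v=rng.uniform(10, 90)
            )
            obs = tuple((float(t), float(rng.uniform(1, 80))) for t in (2.0, 4.0, 6.0))
            s = make_subject(obs=obs)
            want = 0.0
            for t, c in obs:
                mu = pa.conc_profile(point, s.events, t)
                sd = EM.lam + EM.c0 + EM.c1 * c
                want += stats.norm.logpdf(c, loc=mu, scale=sd)
            assert pa.subject_loglik(s, point, EM) == pytest.approx(want, rel=1e-10)


class TestOptimizeWeights:
    def test_single_point(self):
        res = pa.optimize_weights(np.array([[-3.0], [-5.0]]))
        assert res.weights == pytest.approx([1.0])

    def test_dominated_point_gets_no_weight(self):
        L = np.array([[-1.0, -101.0], [-2.0, -102.0], [-3.0, -103.0]])
        res = pa.optimize_weights(L, tol=1e-14, max_iter=20000)
        assert res.weights[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_bruteforce_on_random_two_point_problems(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            L = rng.normal(-2.0, 1.5, size=(3, 2))
            res = pa.optimize_weights(L, tol=1e-14, max_iter=50000)
            w_bf, obj_bf = bruteforce_two_point_weights(L, step=1e-4)
            assert res.objective >= obj_bf - 1e-8
            assert abs(res.weights[0] - w_bf[0]) < 2e-4

    def test_objective_history_non_decreasing(self):
        rng = np.random.default_rng(2)
        L = rng.normal(-5.0, 2.0, size=(10, 8))
        res = pa.optimize_weights(L, tol=1e-12, max_iter=5000)
        diffs = np.diff(res.history)
        assert np.all(diffs >= -1e-9)

    def test_impossible_subject_raises(self):
        L = np.array([[-1.0, -2.0], [-np.inf, -np.inf]])
        with pytest.raises(ValueError, match="1"):
            pa.optimize_weights(L)


class TestPosterior:
    def test_single_support_point(self):
        dist = NPDistribution([PKParams(1.74, 0.135, 44.75)], np.array([1.0]))
        post = pa.posterior(make_subject(), dist, EM)
        assert post.weights == pytest.approx([1.0])
        assert post.mean.ka == pytest.approx(1.74)

    def test_symmetric_likelihoods_give_uniform_posterior(self):
        point = PKParams(ka=1.74, ke=0.135, v=44.75)
        dist = NPDistribution([point, point], np.array([0.5, 0.5]))
        post = pa.posterior(make_subject(), dist, EM)
        assert post.weights == pytest.approx([0.5, 0.5])

    def test_matches_direct_bayes_oracle(self):
        rng = np.random.default_rng(9)
        pts = [
            PKParams(ka=rng.uniform(0.2, 4), ke=rng.uniform(0.05, 0.5), v=rng.uniform(10, 90))
            for _ in range(4)
        ]
        w = rng.dirichlet(np.ones(4))
        dist = NPDistribution(pts, w)
        s = make_subject()
        post = pa.posterior(s, dist, EM)
        lik = np.array([math.exp(pa.subject_loglik(s, p, EM)) for p in pts])
        want = w * lik / (w * lik).sum()
        np.testing.assert_allclose(post.weights, want, rtol=1e-8)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestDiagnostics:
    def _perfect_fit(self):
        point = PKParams(ka=1.74, ke=0.135, v=44.75)
        subjects = []
        for sid, dose in (("a", 20.0), ("b", 40.0)):
            events = (DoseEvent(0.0, dose),)
            obs = tuple(
                Observation(t, pa.conc_profile(point, events, t)) for t in (2.0, 4.0, 6.0)
            )
            subjects.append(SubjectRecord(id=sid, events=events, observations=obs))
        dist = NPDistribution([point], np.array([1.0]))
        posts = {s.id: pa.posterior(s, dist, EM) for s in subjects}
        fitres = FitResult(distribution=dist, loglik=-10.0, n_cycles=1,
                           converged=True, posteriors=posts)
        return fitres, subjects

    def test_perfect_predictions(self):
        fitres, subjects = self._perfect_fit()
        d = pa.diagnostics(fitres, subjects, EM)
        assert d.mwpe == pytest.approx(0.0, abs=1e-12)
        assert d.mwspe == pytest.approx(0.0, abs=1e-12)
        assert d.post_slope == pytest.approx(1.0)
        assert d.post_r == pytest.approx(1.0)
        assert d.n_obs == 6

    def test_information_criteria_use_4k_minus_1_parameters(self):
        fitres, subjects = self._perfect_fit()
        d = pa.diagnostics(fitres, subjects, EM)
        assert d.aic == pytest.approx(-2 * fitres.loglik + 2 * 3)
        assert d.bic == pytest.approx(-2 * fitres.loglik + 3 * math.log(6))

    def test_mwspe_matches_manual_arithmetic(self):
        point = PKParams(ka=1.74, ke=0.135, v=44.75)
        events = (DoseEvent(0.0, 20.0),)
        times = (2.0, 4.0, 6.0)
        preds = [pa.conc_profile(point, events, t) for t in times]
        deltas = (1.5, -2.0, 0.5)
        obs = tuple(Observation(t, p + dlt) for t, p, dlt in zip(times, preds, deltas))
        s = SubjectRecord(id="m", events=events, observations=obs)
        dist = NPDistribution([point], np.array([1.0]))
        fitres = FitResult(distribution=dist, loglik=-1.0, n_cycles=1, converged=True,
                           posteriors={"m": pa.posterior(s, dist, EM)})
        d = pa.diagnostics(fitres, [s], EM)
        manual = [
            dlt / (EM.lam + EM.c0 + EM.c1 * o.conc)
            for dlt, o in zip(deltas, obs)
        ]
        assert d.mwpe == pytest.approx(sum(manual) / 3)
        assert d.mwspe == pytest.approx(sum(e * e for e in manual) / 3)


class TestCovariateScreen:
    def _fitres_with_means(self, means, subjects):
        dist = NPDistribution([PKParams(1.0, 0.1, 40.0)], np.array([1.0]))
        posts = {
            s.id: SubjectPosterior(weights=np.array([1.0]),
                                   mean=PKParams(ka=m[0], ke=m[1], v=m[2]))
            for s, m in zip(subjects, means)
        }
        return FitResult(distribution=dist, loglik=0.0, n_cycles=1,
                         converged=True, posteriors=posts)

    def test_identical_covariate_flagged(self):
        rng = np.random.default_rng(0)
        means = [(rng.uniform(0.5, 3), 0.1, 40.0) for _ in range(20)]
        subjects = [
            make_subject(sid=f"s{i}", covariates={"ck": m[0]})
            for i, m in enumerate(means)
        ]
        tab = pa.covariate_screen(self._fitres_with_means(means, subjects), subjects)
        row = tab[(tab.parameter == "ka") & (tab.covariate == "ck")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.flagged

    def test_permuted_covariate_not_flagged(self):
        rng = np.random.default_rng(1)
        means = [(float(ka), 0.1, 40.0) for ka in rng.uniform(0.5, 3, size=39)]
        cov = rng.permutation([m[0] for m in means])
        subjects = [
            make_subject(sid=f"s{i}", covariates={"chol": float(c)})
            for i, c in enumerate(cov)
        ]
        tab = pa.covariate_screen(self._fitres_with_means(means, subjects), subjects)
        row = tab[(tab.parameter == "ka") & (tab.covariate == "chol")].iloc[0]
        assert abs(row.r) < 0.7 and not row.flagged

    def test_constant_covariate_not_screenable(self):
        means = [(1.0 + i / 10, 0.1, 40.0) for i in range(5)]
        subjects = [
            make_subject(sid=f"s{i}", covariates={"dose": 20.0}) for i in range(5)
        ]
        tab = pa.covariate_screen(self._fitres_with_means(means, subjects), subjects)
        row = tab[tab.covariate == "dose"].iloc[0]
        assert row.kind == "constant" and not row.flagged

    def test_two_level_covariate_type_i_rate_near_one_percent(self):
        rng = np.random.default_rng(7)
        flags = 0
        reps = 400
        for _ in range(reps):
            means = [(float(x), 0.1, 40.0) for x in rng.lognormal(0.5, 0.3, size=39)]
            gender = rng.permutation(["m"] * 19 + ["f"] * 20)
            subjects = [
                make_subject(sid=f"s{i}", covariates={"gender": g})
                for i, g in enumerate(gender)
            ]
            tab = pa.covariate_screen(self._fitres_with_means(means, subjects), subjects)
            row = tab[(tab.parameter == "ka") & (tab.covariate == "gender")].iloc[0]
            flags += bool(row.flagged)
        assert flags / reps < 0.035  # nominal 1% at threshold p < .010


def test_weighted_median_basic():
    assert weighted_median([1.0, 2.0, 3.0], [0.2, 0.5, 0.3]) == 2.0
    assert weighted_median([3.0, 1.0], [0.9, 0.1]) == 3.0
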