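"""Group comparison machinery: rank tests, prediction, CV, PPC mechanics."""

import itertools

import numpy as np
import pytest
from scipy import stats

import ddmcompare as dc
from ddmcompare.cohort import ChoiceRecord, scanner_trials
from ddmcompare.comparison import (_p_distant, kendall_tau, posterior_predictive,
                                   wilcoxon_signed_rank)
from ddmcompare.inference import FitResult


def brute_force_wilcoxon(diffs):
    """Exhaustive sign-flip null distribution of W+ (oracle)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(ranks[np.array(signs, bool)])
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return w_obs, min(1.0, p)


def pair_count_tau(x, y):
    """O(n^2) tau-b oracle."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    _, c = np.unique(v, return_counts=True)
    return np.sum(c * (c - 1) / 2)


class TestWilcoxon:
    def test_rank_enumeration_example(self):
        w, _ = wilcoxon_signed_rank([1, -2, 3])
        assert w == 4.0

    def test_all_negative_gives_zero(self):
        w, _ = wilcoxon_signed_rank([-1, -5, -2])
        assert w == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            d = rng.normal(size=10)
            w, p = wilcoxon_signed_rank(d)
            w_ref, p_ref = brute_force_wilcoxon(d)
            assert w == w_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_matches_scipy_normal_approx(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1, size=40)
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=True, mode="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestKendall:
    def test_perfect_concordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_pair_enumeration_example(self):
        tau, _ = kendall_tau([1, 2, 3], [3, 1, 2])
        assert tau == pytest.approx(-1 / 3)

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            x = rng.integers(0, 8, 15).astype(float)  # ties likely
            y = rng.integers(0, 8, 15).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            tau, _ = kendall_tau(x, y)
            assert tau == pytest.approx(pair_count_tau(x, y), abs=1e-12)

    def test_requires_variation(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])


def _const_fit(params, records, model="attribute"):
    """A FitResult whose posterior is a point mass at the given parameters."""
    vec = params.as_vector()
    draws = np.tile(vec, (2, 10, 1))
    names = ("beta_intercept", "beta_reward", "beta_distance", "alpha",
             "zeta", "tau") if model == "attribute" else (
        "beta_temperature", "log_k", "v_lim", "alpha", "zeta", "tau")
    return FitResult(model=model, participant="p0", task=records[0].trial.task,
                     param_names=names, sampled=names, draws=draws,
                     loglik=np.zeros((len(records), 20)), rhat={},
                     waic=0.0, lppd=0.0, p_waic=0.0,
                     n_trials_used=len(records), n_trials_excluded=0,
                     records=records)


class TestPrediction:
    def _balanced_records(self, n=200):
        trials = scanner_trials("intertemporal", n, rng=1)
        return [ChoiceRecord("p0", t, "upper" if i % 2 else "lower", 1.0)
                for i, t in enumerate(trials)]

    def test_flat_drift_is_chance(self):
        recs = self._balanced_records()
        params = dc.AttributeParams(0.0, 0.0, 0.0, alpha=1.5, zeta=0.5)
        fit = _const_fit(params, recs)
        p, acc = dc.predict_choices(fit)
        assert np.allclose(p, 0.5)
        assert acc == pytest.approx(0.5)  # ties scored half

    def test_high_drift_self_consistency(self):
        params = dc.AttributeParams(2.0, 1.0, -0.02, alpha=2.0, zeta=0.5, tau=0.3)
        trials = scanner_trials("intertemporal", 400, rng=2)
        spec = dc.sample_cohort(1, 1.0, rng=0)[0]
        import dataclasses
        spec = dataclasses.replace(
            spec, attribute_params={t: params for t in spec.attribute_params})
        recs = dc.simulate_behavior(spec, trials, 0.0, rng=3)
        recs = [r for r in recs if not r.omitted]
        fit = _const_fit(params, recs)
        _, acc = dc.predict_choices(fit)
        assert acc > 0.75

    def test_identical_models_never_disagree(self):
        recs = self._balanced_records()
        params = dc.AttributeParams(0.5, 0.4, -0.01, alpha=1.5)
        assert dc.disagreement_rate(_const_fit(params, recs),
                                    _const_fit(params, recs)) == 0.0

    def test_posterior_average_close_to_point_for_tight_posterior(self):
        recs = self._balanced_records(50)
        params = dc.AttributeParams(0.5, 0.4, -0.01, alpha=1.5)
        fit = _const_fit(params, recs)
        p1 = _p_distant(fit, [r.trial for r in recs])
        p2 = _p_distant(fit, [r.trial for r in recs], posterior_average=True)
        assert np.allclose(p1, p2)


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        spec = dc.sample_cohort(1, 1.0, rng=20)[0]
        trials = scanner_trials("intertemporal", 90, rng=21)
        recs = dc.simulate_behavior(spec, trials, 0.06, rng=22)
        kw = dict(repeats=2, samples=600, burn=300)
        m1, _ = dc.cross_validate(recs, "attribute", rng=5, **kw)
        m2, _ = dc.cross_validate(recs, "attribute", rng=5, **kw)
        assert m1 == m2

    def test_too_few_trials_rejected(self):
        trials = scanner_trials("intertemporal", 8, rng=1)
        recs = [ChoiceRecord("p0", t, "upper", 1.0) for t in trials]
        with pytest.raises(ValueError):
            dc.cross_validate(recs, "attribute", repeats=1)


class TestPosteriorPredictive:
    def test_disjoint_supports_give_zero_overlap(self):
        # observed: all closer (negative signed RT); params force distant
        trials = scanner_trials("intertemporal", 80, rng=30)
        recs = [ChoiceRecord("p0", t, "lower", 1.0) for t in trials]
        params = dc.AttributeParams(8.0, 0.5, 0.0, alpha=1.5, zeta=0.5, tau=0.3)
        fit = _const_fit(params, recs)
        _, _, overlap = posterior_predictive(fit, n_sims=500, rng=4)
        assert overlap < 0.05

    def test_overlap_stable_in_n_sims(self, single_fit):
        _, _, fit = single_fit
        _, _, o1 = posterior_predictive(fit, n_sims=1000, rng=5)
        _, _, o2 = posterior_predictive(fit, n_sims=2000, rng=6)
        assert abs(o1 - o2) < 0.02


class TestSanityCorrelations:
    def test_fitted_parameters_track_choice_proportions(self, attribute_cohort,
                                                        attribute_cohort_fits):
        """Summed attribute drift weights rise, and fitted discount rates
        fall, with each participant's propensity for the distant option."""
        _, data = attribute_cohort
        attr_fits = [v["attribute"] for v in attribute_cohort_fits.values()]
        opt_fits = [attribute_cohort_fits[f.participant]["option"]
                    for f in attr_fits]
        rep = dc.sanity_correlations(attr_fits, opt_fits, data)
        assert rep["drift_sum"]["tau"] > 0 and rep["drift_sum"]["p"] < 0.05
        assert rep["log_k"]["tau"] < 0 and rep["log_k"]["p"] < 0.05

    def test_requires_enough_participants(self, attribute_cohort,
                                          attribute_cohort_fits):
        _, data = attribute_cohort
        fits = [v["attribute"] for v in list(attribute_cohort_fits.values())[:5]]
        with pytest.raises(ValueError):
            dc.sanity_correlations(fits, fits, data)
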