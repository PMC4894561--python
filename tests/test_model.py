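import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survnma.families import (
    EffectVector,
    ParamVector,
    apply_effect,
    interval_death_prob,
    untransform_params,
    get_family,
)
from survnma.model import PosteriorDraws, build_model, dic, fit, psrf
from survnma.synthetic import ArmSpec, interval_counts_from_ipd, simulate_arm

from conftest import make_draws, scenario_intervals


def two_arm_intervals(seed=0, n=300, lam_ref=0.05, lam_trt=0.035, horizon=24):
    rows = []
    for trt, lam in (("everolimus", lam_ref), ("nivolumab", lam_trt)):
        ipd = simulate_arm(ArmSpec(trt, n, ParamVector("exponential", (lam,))),
                           censor_rate=0.01, max_followup=40, seed=seed)
        rows.append(interval_counts_from_ipd(ipd, study="s1", treatment=trt,
                                             horizon=horizon))
    return pd.concat(rows, ignore_index=True)


class TestBuildModel:
    def test_two_study_star_parameter_count(self, loglogistic_intervals):
        data, _, _ = loglogistic_intervals
        for family, dim in (("exponential", 1), ("loglogistic", 2)):
            model = build_model(data, family, reference="everolimus")
            assert model.n_params == 2 * dim + 2 * dim
            assert len(model.param_names) == model.n_params

    def test_reference_arm_contributes_through_mu_only(self):
        data = two_arm_intervals()
        model = build_model(data, "exponential", reference="everolimus")
        ref_arm = next(a for a in model.arms if a.effect_idx == -1)
        assert ref_arm.base_idx == -1
        # the delta-dependence of the likelihood lives entirely in the treated
        # arm: truncating the reference rows must not change the delta gradient
        z1 = np.array([np.log(0.05), -0.3])
        z2 = np.array([np.log(0.05), 0.3])
        trimmed = data[(data["treatment"] != "everolimus") | (data["interval_start"] < 12)]
        model_t = build_model(trimmed, "exponential", reference="everolimus")
        full_diff = model.log_likelihood(z1) - model.log_likelihood(z2)
        trim_diff = model_t.log_likelihood(z1) - model_t.log_likelihood(z2)
        assert full_diff == pytest.approx(trim_diff, rel=1e-12)

    def test_log_likelihood_matches_brute_force(self, loglogistic_intervals):
        # independent oracle: per-row binomial logpmf via the scalar family API
        data, _, _ = loglogistic_intervals
        model = build_model(data, "loglogistic", reference="everolimus")
        rng = np.random.default_rng(0)
        z = np.concatenate([
            rng.normal(np.log([19, 1.2]), 0.05).ravel(),  # mu study_A
            rng.normal(np.log([19, 1.2]), 0.05).ravel(),  # mu study_B
            rng.normal(0, 0.1, size=4),                   # deltas
        ])
        spec = get_family("loglogistic")
        studies = model.studies
        treatments = model.treatments
        expected = 0.0
        for _, row in data.iterrows():
            s = studies.index(row["study"])
            mu = ParamVector("loglogistic", tuple(untransform_params(spec, z[2 * s: 2 * s + 2])))
            if row["treatment"] == "everolimus":
                theta = mu
            else:
                k = treatments.index(row["treatment"])
                theta = apply_effect(mu, EffectVector("loglogistic", tuple(z[4 + 2 * k: 6 + 2 * k])))
            ntrials = int(row["n_at_risk"] - row["censored"])
            if ntrials == 0:
                continue
            p = interval_death_prob(theta, row["interval_start"], row["interval_start"] + 1)
            expected += stats.binom.logpmf(int(row["deaths"]), ntrials, p)
        assert model.log_likelihood(z) == pytest.approx(expected, rel=1e-10)

    def test_disconnected_network_error(self):
        a = two_arm_intervals()
        b = two_arm_intervals().assign(study="s2")
        b["treatment"] = b["treatment"].map(
            {"everolimus": "drugX", "nivolumab": "drugY"}
        )
        data = pd.concat([a, b], ignore_index=True)
        with pytest.raises(ValueError, match="disconnected"):
            build_model(data, "exponential", reference="everolimus")

    def test_missing_reference_everywhere_errors(self):
        data = two_arm_intervals()
        with pytest.raises(ValueError, match="appears in no study"):
            build_model(data, "exponential", reference="pembrolizumab")

    def test_single_arm_study_errors(self):
        data = two_arm_intervals()
        with pytest.raises(ValueError, match="fewer than 2"):
            build_model(data[data["treatment"] == "everolimus"], "exponential",
                        reference="everolimus")


class TestFit:
    def test_exponential_posterior_close_to_mle(self):
        data = two_arm_intervals(seed=14, n=400)
        model = build_model(data, "exponential", reference="everolimus")
        draws = fit(model, chains=2, iterations=4000, burn_in=2000, seed=1)
        # closed-form discrete-time MLE for the reference arm
        ref = data[data["treatment"] == "everolimus"]
        trials = (ref["n_at_risk"] - ref["censored"]).sum()
        deaths = ref["deaths"].sum()
        lam_mle = -np.log(1 - deaths / trials)
        lam_post = np.exp(draws.mu("s1")[:, 0]).mean()
        assert lam_post == pytest.approx(lam_mle, rel=0.05)

    def test_identical_arms_delta_covers_zero(self):
        data = two_arm_intervals(seed=6, n=300, lam_ref=0.05, lam_trt=0.05)
        model = build_model(data, "exponential", reference="everolimus")
        draws = fit(model, chains=2, iterations=4000, burn_in=2000, seed=2)
        d = draws.delta("nivolumab")[:, 0]
        lo, hi = np.percentile(d, [2.5, 97.5])
        assert lo < 0 < hi

    def test_iterations_must_exceed_burn_in(self):
        data = two_arm_intervals()
        model = build_model(data, "exponential", reference="everolimus")
        with pytest.raises(ValueError):
            fit(model, iterations=100, burn_in=100, seed=0)

    def test_seed_reproducibility(self):
        data = two_arm_intervals(seed=3, n=150)
        model = build_model(data, "exponential", reference="everolimus")
        a = fit(model, chains=2, iterations=800, burn_in=400, seed=11)
        b = fit(model, chains=2, iterations=800, burn_in=400, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestPSRF:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(500, 3))
        val = psrf(np.stack([chain, chain]))
        np.testing.assert_allclose(val, 1.0, atol=1e-6)

    def test_same_target_long_run_below_101(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, 5000, 2))
        assert np.all(psrf(arr) < 1.01)

    def test_disjoint_supports_explode(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(1000, 1))
        b = rng.normal(50, 1, size=(1000, 1))
        assert psrf(np.stack([a, b]))[0] > 10

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((1, 100, 2)))

    def test_named_output(self, exponential_fit):
        model, draws = exponential_fit
        values = psrf(draws)
        assert set(values) == set(model.param_names)
        assert max(values.values()) < 1.02


class TestDIC:
    def test_degenerate_posterior_pd_zero(self):
        data = two_arm_intervals(seed=5, n=100)
        model = build_model(data, "exponential", reference="everolimus")
        z = np.array([np.log(0.05), np.log(0.8)])
        samples = np.broadcast_to(z, (2, 200, 2)).copy()
        draws = make_draws(samples, model.param_names, "exponential",
                           model.studies, model.treatments)
        d, p_d, mean_dev = dic(draws, model)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert d == pytest.approx(mean_dev)
        assert d == pytest.approx(float(model.deviance(z)))

    def test_replicate_runs_agree(self):
        data = two_arm_intervals(seed=9, n=300)
        model = build_model(data, "exponential", reference="everolimus")
        dics = []
        for seed in (21, 22):
            draws = fit(model, chains=2, iterations=4000, burn_in=2000, seed=seed)
            dics.append(dic(draws, model)[0])
        assert abs(dics[0] - dics[1]) < 2.0

    def test_family_selection_direction(self, loglogistic_fit, exponential_fit):
        ll_model, ll_draws, _, _ = loglogistic_fit
        e_model, e_draws = exponential_fit
        assert dic(ll_draws, ll_model)[0] < dic(e_draws, e_model)[0]


class TestRelabelingInvariance:
    def test_baseline_relabeling_leaves_contrasts_unchanged(self):
        data, _, _ = scenario_intervals(seed=77, n_per_arm=250)
        kwargs = dict(chains=2, iterations=4000, burn_in=2000)
        m1 = build_model(data, "exponential", reference="everolimus")
        d1 = fit(m1, seed=31, **kwargs)
        m2 = build_model(data, "exponential", reference="everolimus",
                         baselines={"study_A": "nivolumab"})
        d2 = fit(m2, seed=32, **kwargs)
        for trt in ("nivolumab", "cabozantinib"):
            a = np.exp(d1.delta(trt)[:, 0])
            b = np.exp(d2.delta(trt)[:, 0])
            assert np.median(a) == pytest.approx(np.median(b), rel=0.05)


class TestPosteriorDraws:
    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            make_draws(np.zeros((1, 10, 2)), ["a", "b"], "exponential", ["s"], ["t"])

    def test_arm_z_composition(self, loglogistic_fit):
        _, draws, _, _ = loglogistic_fit
        z = draws.arm_z("study_A", "nivolumab")
        np.testing.assert_allclose(
            z, draws.mu("study_A") + draws.delta("nivolumab"), atol=1e-12
        )

    def test_reference_delta_is_zero(self, loglogistic_fit):
        _, draws, _, _ = loglogistic_fit
        assert not draws.delta("everolimus").any()


def test_psrf_cross_checked_against_arviz(exponential_fit):
    az = pytest.importorskip("arviz")
    _, draws = exponential_fit
    ours = psrf(draws.samples)
    # classic (non-rank-normalized) Gelman-Rubin should agree closely with
    # arviz's rhat for well-mixed chains
    theirs = np.array([
        float(az.rhat(draws.samples[:, :, j])) for j in range(draws.samples.shape[2])
    ])
    np.testing.assert_allclose(ours, theirs, atol=0.01)
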