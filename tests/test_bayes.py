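import numpy as np
import pandas as pd
import pytest

from affectdyn import (
    GroupDesign,
    McmcConfig,
    PriorSpec,
    build_lagged,
    convergence_report,
    extract_outcome,
    group_contrast_summary,
    posterior_person_means,
    run_mcmc,
    shrink_factor,
    simulate_study,
)
from affectdyn.bayes import COMPONENTS, PosteriorDraws, split_shrink_factor
from tests.conftest import three_group_config

EMPTY = pd.DataFrame(columns=["person_id", "group", "y", "x"])


def single_group_frame(n_persons=8, n_obs=6, tau=0.8, sigma=1.0, mu0=2.0, seed=0):
    """Normal-normal data: y_tij ~ N(mu_i, sigma^2), mu_i ~ N(mu0, tau^2), x = 0."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_persons):
        mu_i = rng.normal(mu0, tau)
        for t in range(n_obs):
            rows.append({"person_id": f"p{i}", "group": "A", "day": 0, "prompt_index": t,
                         "y": rng.normal(mu_i, sigma), "x": 0.0})
    return pd.DataFrame(rows)


class TestRunMcmc:
    def test_conjugate_oracle(self):
        # collapsed sub-model: person variances and the population covariance
        # held fixed, no slope information (x = 0), single group -> the group
        # homebase mean has a normal-normal closed-form posterior
        tau, sigma, n_obs = 0.8, 1.0, 6
        frame = single_group_frame(tau=tau, sigma=sigma, n_obs=n_obs)
        design = GroupDesign("A", {})
        cfg = McmcConfig(
            n_chains=4, burn_in=500, keep=2500, seed=3,
            fixed_pop_cov=np.diag([tau**2, 0.01, 0.01]),
            fixed_person_log_var=np.full(8, 2 * np.log(sigma)),
        )
        draws = run_mcmc(frame, design, config=cfg)
        got = draws.flat("mean_homebase")

        ybar = frame.groupby("person_id")["y"].mean().sort_index().to_numpy()
        w = 1.0 / (tau**2 + sigma**2 / n_obs)
        prec = 1.0 / 1000.0 + len(ybar) * w
        post_mean = (w * ybar.sum()) / prec
        post_sd = np.sqrt(1.0 / prec)

        mcse = got.std() / np.sqrt(len(got) / 20)  # conservative ESS deflation
        assert abs(got.mean() - post_mean) < 3 * mcse
        assert got.std() == pytest.approx(post_sd, rel=0.10)

    def test_prior_only_run(self):
        # no data: group-level draws must reproduce the priors
        design = GroupDesign("A", {"B": "B"})
        cfg = McmcConfig(n_chains=4, burn_in=200, keep=2500, seed=5)
        draws = run_mcmc(EMPTY, design, config=cfg)
        for p in ("mean_homebase", "mean_logvar", "diff_homebase[B]"):
            sd = draws.flat(p).std()
            assert abs(sd - np.sqrt(1000)) < 0.05 * np.sqrt(1000)
        for p in ("mean_autoreg", "diff_autoreg[B]"):
            v = draws.flat(p)
            assert v.min() > -1 and v.max() < 1

    def test_prior_only_pop_cov_moments(self):
        # inverse-Wishart(I, 4) marginals: E[Sigma_ii] = 1/(df - p - 1) is
        # undefined at df=4, but the precision Sigma^-1 ~ Wishart(I, 4) has
        # E[(Sigma^-1)_ii] = df = 4; check via the sampled matrices
        design = GroupDesign("A", {})
        cfg = McmcConfig(n_chains=2, burn_in=10, keep=4000, seed=11)
        draws = run_mcmc(EMPTY, design, config=cfg)
        idx = {(i, j): f"pop_cov[{i},{j}]" for i in range(3) for j in range(i, 3)}
        precs = []
        for c in range(2):
            for t in range(0, 4000, 4):
                S = np.empty((3, 3))
                for (i, j), name in idx.items():
                    S[i, j] = S[j, i] = draws.sel(name)[c, t]
                precs.append(np.diag(np.linalg.inv(S)))
        mean_prec = np.mean(precs, axis=0)
        assert np.all(np.abs(mean_prec - 4.0) < 0.4)

    def test_recovery_three_groups(self, small_study):
        cfg, _, lagged, design = small_study
        draws = run_mcmc(lagged, design, config=McmcConfig(n_chains=4, burn_in=800, keep=800, seed=2))
        truth = {
            "mean_homebase": 5.0, "mean_autoreg": 0.3, "mean_logvar": 0.0,
            "diff_homebase[PD]": -2.0, "diff_homebase[MD]": -1.3,
            "diff_autoreg[PD]": -0.1, "diff_autoreg[MD]": 0.05,
            "diff_logvar[PD]": 0.3, "diff_logvar[MD]": 0.1,
        }
        for p, t in truth.items():
            v = draws.flat(p)
            assert abs(v.mean() - t) < 3 * v.std(), f"{p}: {v.mean():.3f} vs {t}"

    def test_pop_cov_draws_psd(self, small_study):
        _, _, lagged, design = small_study
        draws = run_mcmc(lagged, design, config=McmcConfig(n_chains=2, burn_in=100, keep=50, seed=9))
        for c in range(2):
            for t in range(50):
                S = np.empty((3, 3))
                for i in range(3):
                    for j in range(i, 3):
                        S[i, j] = S[j, i] = draws.sel(f"pop_cov[{i},{j}]")[c, t]
                assert np.all(np.linalg.eigvalsh(S) > 0)

    def test_seed_determinism(self):
        frame = single_group_frame()
        design = GroupDesign("A", {})
        cfg = McmcConfig(n_chains=2, burn_in=50, keep=50, seed=7)
        d1 = run_mcmc(frame, design, config=cfg)
        d2 = run_mcmc(frame, design, config=cfg)
        np.testing.assert_array_equal(d1.array, d2.array)

    def test_degenerate_person_rejected(self):
        frame = pd.DataFrame([{"person_id": "p", "group": "A", "y": 1.0, "x": 0.0}])
        with pytest.raises(ValueError, match="fewer than 2"):
            run_mcmc(frame, GroupDesign("A", {}), config=McmcConfig(n_chains=1, burn_in=1, keep=1))

    def test_bad_prior_spec(self):
        with pytest.raises(ValueError):
            PriorSpec(fixed_effect_variance=-1)
        with pytest.raises(ValueError):
            PriorSpec(wishart_df=2)


class TestShrinkFactor:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=1000)
        chains = np.stack([one, one, one])
        assert shrink_factor(chains, None) == pytest.approx(np.sqrt(999 / 1000), abs=1e-12)

    def test_separated_chains_analytic(self):
        # two chains at N(0,1) and N(10,1): B = n * 50 + O(noise), W ~ 1,
        # so PSRF ~ sqrt((n-1)/n + B/(n W)) ~ sqrt(51)
        rng = np.random.default_rng(1)
        n = 1000
        chains = np.stack([rng.normal(0, 1, n), rng.normal(10, 1, n)])
        W = chains.var(axis=1, ddof=1).mean()
        B = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        got = shrink_factor(chains, None)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 1.1
        assert got == pytest.approx(np.sqrt(51), rel=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            shrink_factor(np.zeros((1, 100)), None)

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            shrink_factor(np.zeros((2, 5)), None)

    def test_split_variant_detects_trend(self):
        # half-and-half drift within each chain: classic P SRF misses it, split sees it
        n = 2000
        drift = np.concatenate([np.zeros(n // 2), np.full(n // 2, 5.0)])
        rng = np.random.default_rng(2)
        chains = np.stack([drift + rng.normal(0, 0.1, n), drift + rng.normal(0, 0.1, n)])
        assert shrink_factor(chains, None) < 1.1
        assert split_shrink_factor(chains, None) > 1.1

    def test_convergence_report(self, small_study):
        _, _, lagged, design = small_study
        draws = run_mcmc(lagged, design, config=McmcConfig(n_chains=4, burn_in=400, keep=400, seed=4))
        rep = convergence_report(draws)
        assert set(rep.psrf.index) == set(draws.group_level_names)
        assert rep.worst >= rep.psrf.min()
        # >= 1 up to estimator noise: the formula's floor is sqrt((n-1)/n)
        assert (rep.psrf >= np.sqrt(399 / 400) - 1e-12).all()
        d = rep.to_dict()
        assert d["worst"] == rep.worst


def rigged_draws(values_by_param, person_ids=("p1",), groups=("A",), design=None):
    """Build a PosteriorDraws with hand-set (chain, iteration) arrays."""
    design = design or GroupDesign("A", {})
    names = list(values_by_param)
    arrs = [np.asarray(values_by_param[p], float) for p in names]
    array = np.stack(arrs, axis=-1)
    return PosteriorDraws(array, names, list(person_ids), list(groups), design)


class TestSummaries:
    def test_person_means_single_iteration(self):
        vals = {
            "person_homebase[p1]": [[3.0]],
            "person_autoreg[p1]": [[0.5]],
            "person_logvar[p1]": [[0.0]],
        }
        pm = posterior_person_means(rigged_draws(vals))
        assert pm.iloc[0]["homebase"] == 3.0
        assert pm.iloc[0]["autocorrelation"] == 0.5
        assert pm.iloc[0]["within_variance"] == 1.0

    def test_person_means_two_point_chain(self):
        a, b = 1.0, 5.0
        vals = {
            "person_homebase[p1]": [[a, b]],
            "person_autoreg[p1]": [[a, b]],
            "person_logvar[p1]": [[np.log(a), np.log(b)]],
        }
        pm = posterior_person_means(rigged_draws(vals))
        assert pm.iloc[0]["homebase"] == (a + b) / 2
        # variance scale: mean of exp(log-variance), not exp of the mean
        assert pm.iloc[0]["within_variance"] == pytest.approx((a + b) / 2, rel=1e-12)
        pm_log = posterior_person_means(rigged_draws(vals), variance_scale="log")
        assert pm_log.iloc[0]["within_variance"] == pytest.approx((np.log(a) + np.log(b)) / 2, rel=1e-12)

    def test_group_ordering_recovered(self, small_study):
        _, _, lagged, design = small_study
        draws = run_mcmc(lagged, design, config=McmcConfig(n_chains=2, burn_in=400, keep=400, seed=6))
        pm = posterior_person_means(draws)
        means = pm.groupby("group")["homebase"].mean()
        assert means["BPD"] > means["MD"] > means["PD"]  # truth: 5.0 > 3.7 > 3.0

    def test_contrast_constant_draws(self):
        design = GroupDesign("A", {"B": "B"})
        vals = {f"diff_{c}[B]": [[2.5, 2.5, 2.5]] for c in COMPONENTS}
        summary = group_contrast_summary(rigged_draws(vals, design=design))
        assert (summary["lo"] == 2.5).all() and (summary["hi"] == 2.5).all()
        assert summary["supported"].all()

    def test_contrast_centered_draws_not_supported(self):
        design = GroupDesign("A", {"B": "B"})
        rng = np.random.default_rng(0)
        vals = {f"diff_{c}[B]": rng.normal(0, 1, (2, 500)) for c in COMPONENTS}
        summary = group_contrast_summary(rigged_draws(vals, design=design))
        assert not summary["supported"].any()

    def test_chain_permutation_invariance(self):
        frame = single_group_frame()
        design = GroupDesign("A", {})
        draws = run_mcmc(frame, design, config=McmcConfig(n_chains=3, burn_in=50, keep=100, seed=8))
        permuted = draws.permute_chains([2, 0, 1])
        assert shrink_factor(draws, "mean_homebase") == pytest.approx(
            shrink_factor(permuted, "mean_homebase"), abs=1e-14)
        pd.testing.assert_frame_equal(posterior_person_means(draws), posterior_person_means(permuted))


class TestFrameworkAgreement:
    def test_bayes_matches_frequentist(self, small_study):
        # dual-framework robustness: group-level posterior means vs ML estimates
        from affectdyn import fit_mels

        _, _, lagged, design = small_study
        fit = fit_mels(lagged, design, seed=1)
        draws = run_mcmc(lagged, design, config=McmcConfig(n_chains=4, burn_in=800, keep=800, seed=3))
        pairs = {
            "mean_homebase": "homebase:intercept",
            "diff_homebase[PD]": "homebase:PD",
            "diff_homebase[MD]": "homebase:MD",
            "mean_autoreg": "autoreg:intercept",
            "diff_autoreg[PD]": "autoreg:PD",
            "diff_autoreg[MD]": "autoreg:MD",
        }
        for bp, fp in pairs.items():
            post = draws.flat(bp)
            j = fit.beta_names.index(fp)
            joint_se = np.sqrt(post.var() + fit.beta_se[j] ** 2)
            assert abs(post.mean() - fit.beta[j]) < 3 * joint_se, bp
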