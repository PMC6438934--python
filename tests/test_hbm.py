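"""Gibbs sampler: conjugate oracle, determinism, diagnostics, predictive."""

import numpy as np
import pytest
from scipy import stats

import twinefw as tw
from twinefw.hbm import RandomSlopeGibbs, sample_invwishart


def _toy_regression(n=60, seed=3):
    rng = np.random.default_rng(seed)
    w = rng.uniform(16, 37, n)
    y = 5.0 + 1.2 * w + rng.normal(0, 1.0, n)
    groups = [f"G{i % 6}" for i in range(n)]
    return w, y, groups


def _fake_draws(k=5000, seed=0, sigma2=1.0, Sigma=None, beta=(-20.0, 1.9)):
    rng = np.random.default_rng(seed)
    b = np.tile(np.asarray(beta, dtype=float), (k, 1))
    S = np.tile(np.zeros((2, 2)) if Sigma is None else np.asarray(Sigma), (k, 1, 1))
    return tw.PosteriorDraws(beta=b, Sigma_u=S, sigma2_e=np.full(k, sigma2))


# ---------------------------------------------------------------------------
# conjugate oracle


def test_gibbs_matches_closed_form_posterior_in_conjugate_case():
    """Random effects pinned at zero + known residual variance make the
    posterior of beta a normal-normal conjugate update; the sampler's draws
    must reproduce its mean (to 3 MC standard errors) and covariance."""
    w, y, groups = _toy_regression()
    est = RandomSlopeGibbs(
        random_effects=False, fixed_sigma2_e=1.0, n_keep=4000, thin=1, burn_in=100, seed=9
    )
    est.fit(w[:, None], y, groups=groups)
    mean, cov = tw.conjugate_beta_posterior(w, y, sigma2_e=1.0)
    draws = est.beta_draws_
    for j in range(2):
        mc_se = draws[:, j].std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws[:, j].mean() - mean[j]) < 3 * mc_se
        assert draws[:, j].var(ddof=1) == pytest.approx(cov[j, j], rel=0.15)
    assert np.cov(draws.T)[0, 1] == pytest.approx(cov[0, 1], rel=0.2)


def test_invwishart_sampler_convention_agrees_with_scipy():
    """Our Bartlett-based draw and scipy.stats.invwishart share the
    E[Sigma] = scale/(df-p-1) convention."""
    df, scale = 10.0, np.array([[2.0, 0.3], [0.3, 5.0]])
    rng = np.random.default_rng(0)
    mine = np.mean([sample_invwishart(rng, df, scale) for _ in range(4000)], axis=0)
    analytic = scale / (df - 3.0)
    assert np.allclose(mine, analytic, rtol=0.08)
    assert np.allclose(stats.invwishart(int(df), scale).mean(), analytic)
    with pytest.raises(ValueError):
        sample_invwishart(rng, 1.0, scale)


# ---------------------------------------------------------------------------
# reproducibility contracts


def test_same_seed_gives_bit_identical_draws():
    w, y, groups = _toy_regression()
    kw = dict(n_keep=200, thin=2, burn_in=100, seed=4)
    a = RandomSlopeGibbs(**kw).fit(w[:, None], y, groups=groups)
    b = RandomSlopeGibbs(**kw).fit(w[:, None], y, groups=groups)
    assert np.array_equal(a.beta_draws_, b.beta_draws_)
    assert np.array_equal(a.Sigma_u_draws_, b.Sigma_u_draws_)
    assert np.array_equal(a.sigma2_e_draws_, b.sigma2_e_draws_)
    c = RandomSlopeGibbs(**{**kw, "seed": 5}).fit(w[:, None], y, groups=groups)
    assert not np.array_equal(a.beta_draws_, c.beta_draws_)


def test_relabeling_groups_leaves_draws_unchanged():
    w, y, groups = _toy_regression()
    renamed = [f"pregnancy-{g}" for g in groups]
    kw = dict(n_keep=150, thin=1, burn_in=50, seed=8)
    a = RandomSlopeGibbs(**kw).fit(w[:, None], y, groups=groups)
    b = RandomSlopeGibbs(**kw).fit(w[:, None], y, groups=renamed)
    assert np.array_equal(a.beta_draws_, b.beta_draws_)


def test_posterior_contraction_with_sample_size(truth):
    """Doubling the number of pregnancies shrinks the posterior sd of the
    slope, on average over seeds."""
    def post_sd(n, seed):
        _, exams, _ = tw.generate_cohort(truth, n, seed=seed)
        draws = tw.fit_gibbs(
            exams, config=tw.ModelConfig(n_keep=250, thin=2, burn_in=250, seed=seed)
        )
        return draws.beta[:, 1].std(ddof=1)

    small = np.mean([post_sd(25, s) for s in (1, 2, 3)])
    large = np.mean([post_sd(50, s) for s in (1, 2, 3)])
    assert large < small


# ---------------------------------------------------------------------------
# input validation


def test_empty_and_malformed_inputs():
    est = RandomSlopeGibbs(n_keep=10, thin=1, burn_in=1)
    with pytest.raises(ValueError, match="empty"):
        est.fit(np.empty((0, 1)), np.empty(0), groups=[])
    with pytest.raises(ValueError, match="groups"):
        est.fit(np.ones((3, 1)), np.ones(3))
    with pytest.raises(ValueError, match="at least 2"):
        est.fit(np.ones((3, 1)), np.ones(3), groups=["a", "a", "a"])
    with pytest.raises(ValueError):
        tw.fit_gibbs([], config=tw.ModelConfig(n_keep=10, thin=1, burn_in=1))


def test_single_visit_per_pregnancy_warns_not_fails():
    rng = np.random.default_rng(1)
    w = np.repeat([20.0, 24.0, 28.0, 32.0], 2)  # one visit per pregnancy, 2 fetuses
    groups = np.repeat(["a", "b", "c", "d"], 2)
    y = 1.9 * w - 20 + rng.normal(0, 1, len(w))
    with pytest.warns(UserWarning, match="replication"):
        RandomSlopeGibbs(n_keep=20, thin=1, burn_in=10, seed=0).fit(
            w[:, None], y, groups=list(groups)
        )


def test_model_config_validation():
    with pytest.raises(ValueError):
        tw.ModelConfig(n_keep=0)
    with pytest.raises(ValueError):
        tw.ModelConfig(thin=-1)
    with pytest.raises(ValueError):
        tw.ModelConfig(iw_scale=(0.0, 20.0))


# ---------------------------------------------------------------------------
# posterior predictive


def test_predictive_degenerate_draws_collapse_to_the_line():
    draws = _fake_draws(k=500, sigma2=0.0)
    s = tw.posterior_predictive(draws, 28, seed=0)
    assert np.allclose(s, -20.0 + 1.9 * 28)


def test_predictive_moments_with_pure_residual_noise():
    draws = _fake_draws(k=20000, sigma2=1.0)
    s = tw.posterior_predictive(draws, 30, seed=1)
    mu = -20.0 + 1.9 * 30
    assert s.mean() == pytest.approx(mu, abs=3 / np.sqrt(len(s)))
    assert s.std(ddof=1) == pytest.approx(1.0, abs=0.02)


def test_predictive_week_grid_guard():
    draws = _fake_draws(k=200)
    with pytest.raises(ValueError, match="grid"):
        tw.posterior_predictive(draws, 45, seed=0)
    out = tw.posterior_predictive(draws, 45, seed=0, extrapolate=True)
    assert len(out) == 200


def test_draws_csv_round_trip(tmp_path):
    draws = _fake_draws(k=50, sigma2=1.3, Sigma=np.array([[2.0, 0.1], [0.1, 0.05]]))
    draws.meta["seed"] = 7
    draws.save(tmp_path / "d.csv", tmp_path / "d.json")
    again = tw.PosteriorDraws.load(tmp_path / "d.csv", tmp_path / "d.json")
    assert np.allclose(again.beta, draws.beta)
    assert np.allclose(again.Sigma_u, draws.Sigma_u)
    assert again.meta["seed"] == 7


# ---------------------------------------------------------------------------
# diagnostics


def test_ess_of_independent_chain_is_near_its_length():
    rng = np.random.default_rng(2)
    k = 5000
    draws = tw.PosteriorDraws(
        beta=rng.normal(size=(k, 2)),
        Sigma_u=np.tile(np.eye(2), (k, 1, 1)) * (1 + rng.random(k))[:, None, None],
        sigma2_e=rng.gamma(5, 1, k),
    )
    diag = tw.diagnostics(draws)
    assert diag.loc["beta0", "ess"] == pytest.approx(k, rel=0.2)
    assert not diag["flagged"].any()


def test_constant_chain_reported_degenerate_not_crash():
    draws = _fake_draws(k=500, sigma2=1.0)
    diag = tw.diagnostics(draws)
    assert diag.loc["beta0", "degenerate"]
    assert np.isnan(diag.loc["beta0", "ess"])


def test_diagnostics_require_enough_draws():
    with pytest.raises(ValueError, match="100"):
        tw.diagnostics(_fake_draws(k=50))


def test_converged_recovery_chains_pass_geweke(full_run):
    diag = tw.diagnostics(full_run["draws"])
    assert not diag.loc["beta0", "flagged"]
    assert not diag.loc["beta1", "flagged"]


def test_recovery_run_posterior_covers_truth(full_run):
    """Posterior means of beta and sigma2_e land within 3 posterior sds of
    the generating truth in the scaled-down study replica."""
    truth, draws = full_run["truth"], full_run["draws"]
    for j, target in ((0, truth.beta0), (1, truth.beta1)):
        x = draws.beta[:, j]
        assert abs(x.mean() - target) < 3 * x.std(ddof=1)
    s2 = draws.sigma2_e
    assert abs(s2.mean() - truth.sigma2_e) < 3 * s2.std(ddof=1)
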