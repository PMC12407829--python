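import math

import numpy as np
import pytest
from scipy import stats

import normbench as nb
from normbench.model import (NormativeModelResults, WarpedBLR,
                             negative_log_likelihood)
from normbench.shash import shash_derivative, shash_warp


def _naive_nll(theta, phi, y):
    """Direct-summation oracle for the warped negative log evidence."""
    log_alpha, log_beta, a, log_b = theta
    alpha, beta, b = math.exp(log_alpha), math.exp(log_beta), math.exp(log_b)
    n, d = phi.shape
    yt = shash_warp(y, a, b)
    a_mat = alpha * np.eye(d) + beta * phi.T @ phi
    mu = beta * np.linalg.solve(a_mat, phi.T @ yt)
    energy = 0.5 * beta * np.sum((yt - phi @ mu) ** 2) + 0.5 * alpha * mu @ mu
    sign, logdet = np.linalg.slogdet(a_mat)
    assert sign > 0
    evidence = (0.5 * d * math.log(alpha) + 0.5 * n * math.log(beta) - energy
                - 0.5 * logdet - 0.5 * n * math.log(2 * math.pi))
    jac = np.sum(np.log(shash_derivative(y, a, b)))
    return -evidence - jac


def test_nll_hand_worked_example():
    """N=2, D=1, Phi=[1,1]', y=[0,2], alpha=beta=1, identity warp:
    A = 3, mu_w = 2/3, E = 4/3, NLL = 4/3 + ln(3)/2 + ln(2 pi)."""
    phi = np.array([[1.0], [1.0]])
    y = np.array([0.0, 2.0])
    expected = 4.0 / 3.0 + 0.5 * math.log(3.0) + math.log(2 * math.pi)
    got = negative_log_likelihood((0.0, 0.0, 0.0, 0.0), phi, y)
    assert got == pytest.approx(expected, abs=1e-10)
    model = WarpedBLR(y, phi, standardize=False)
    mu_w, a_mat = model.posterior(1.0, 1.0)
    assert mu_w[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
    assert a_mat[0, 0] == pytest.approx(3.0, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_nll_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    phi = rng.normal(size=(10, 3))
    y = rng.normal(size=10)
    model = WarpedBLR(y, phi, standardize=False)
    for theta in rng.normal(scale=0.5, size=(5, 4)):
        assert model.nloglike(theta) == pytest.approx(
            _naive_nll(theta, phi, y), rel=1e-9)


def test_identity_warp_posterior_equals_closed_form_blr():
    """With (a, b) frozen at (0, 1) the weight posterior is the textbook
    Bayesian ridge solution (tolerance 1e-8)."""
    rng = np.random.default_rng(3)
    phi = rng.normal(size=(40, 5))
    y = rng.normal(size=40)
    model = WarpedBLR(y, phi, standardize=False)
    alpha, beta = 0.7, 2.3
    mu_w, a_mat = model.posterior(alpha, beta)
    a_ref = alpha * np.eye(5) + beta * phi.T @ phi
    mu_ref = beta * np.linalg.solve(a_ref, phi.T @ y)
    np.testing.assert_allclose(mu_w, mu_ref, atol=1e-8)
    np.testing.assert_allclose(a_mat, a_ref, atol=1e-8)
    # the penalized precision is positive definite even for a collinear design
    phi_coll = np.hstack([phi, phi[:, :1]])
    _, a_coll = WarpedBLR(y, phi_coll, standardize=False).posterior(alpha, beta)
    assert np.all(np.linalg.eigvalsh(a_coll) > 0)


def test_optimizer_never_worse_than_start(small_pool):
    model = WarpedBLR.from_cohort(small_pool, "roi-001")
    res = model.fit()
    assert res.nll <= model.nloglike((0.0, 0.0, 0.0, 0.0)) + 1e-9


def test_warp_parameter_recovery_on_model_true_data():
    """(a, b) = (0.3, 1.4) recovered within +/-0.1 and the effective noise
    precision within 15% at n = 5000."""
    spec = nb.CohortSpec(n_rois=1, n_hc=5000, n_ad=0, warp_true=(0.3, 1.4),
                         seed=41)
    table, truth = nb.generate_cohort(spec, return_truth=True)
    res = WarpedBLR.from_cohort(table, "roi-001").fit()
    assert res.warp.a == pytest.approx(0.3, abs=0.1)
    assert res.warp.b == pytest.approx(1.4, abs=0.1)
    beta_eff = truth["beta_eff"].iloc[0]
    assert res.beta == pytest.approx(beta_eff, rel=0.15)


def test_null_warp_recovery_on_gaussian_data(gaussian_cohort):
    res = WarpedBLR.from_cohort(gaussian_cohort, "roi-001").fit()
    assert abs(res.warp.a) < 0.05
    assert 0.9 < res.warp.b < 1.1


def test_tiny_training_set_completes_without_crash(small_pool):
    """n = 5 fits either converge or come back flagged, never crash."""
    sub = small_pool.head(5)
    with pytest.warns(RuntimeWarning):
        model = WarpedBLR.from_cohort(sub, "roi-001")
        res = model.fit()
    assert isinstance(res.converged, bool)
    assert np.isfinite(res.nll)


def test_predict_hand_worked_example():
    """Intercept-only model from the NLL example: mu* = 2/3, total
    variance 1 + 1/3 = 4/3."""
    phi = np.array([[1.0], [1.0]])
    y = np.array([0.0, 2.0])
    model = WarpedBLR(y, phi, standardize=False)
    res = NormativeModelResults(model, (0.0, 0.0, 0.0, 0.0))
    pred = res.predict(np.array([[1.0]]))
    assert pred.mu_warped[0] == pytest.approx(2.0 / 3.0)
    assert pred.total_sd[0] ** 2 == pytest.approx(4.0 / 3.0)
    assert pred.aleatoric_var == pytest.approx(1.0)
    assert pred.epistemic_var[0] == pytest.approx(1.0 / 3.0)
    # identity warp, no standardizer: point prediction equals mu*
    assert pred.point_prediction[0] == pytest.approx(2.0 / 3.0)


def test_epistemic_uncertainty_shrinks_with_data(small_pool):
    sizes = [30, 100, 300]
    probe = small_pool.head(20)
    epi = []
    for n in sizes:
        res = WarpedBLR.from_cohort(small_pool.head(n), "roi-001").fit()
        epi.append(res.predict(probe).epistemic_var.mean())
    assert epi[0] > epi[1] > epi[2]


def test_zscore_zero_at_predicted_mean(small_models, small_pool):
    res = small_models["roi-001"]
    probe = small_pool.head(10).copy()
    probe["roi-001"] = res.predict(probe).point_prediction
    np.testing.assert_allclose(res.zscore(probe), 0.0, atol=1e-8)


def test_zscore_sign_convention_atrophy_negative(small_models, small_pool):
    """Values far below the normative curve give z < -1.96."""
    res = small_models["roi-001"]
    probe = small_pool.head(10).copy()
    pred = res.predict(probe)
    probe["roi-001"] = pred.point_prediction - 10 * res.model.y_sd
    assert (res.zscore(probe) < -1.96).all()


def test_zscore_missing_value_propagates(small_models, small_pool):
    res = small_models["roi-001"]
    probe = small_pool.head(5).copy()
    probe.loc[probe.index[2], "roi-001"] = np.nan
    z = res.zscore(probe)
    assert np.isnan(z[2]) and np.isfinite(np.delete(z, 2)).all()


def test_hc_test_zscores_standard_normal():
    """Calibration on model-true data: Z ~ N(0,1) on held-out HC."""
    spec = nb.CohortSpec(n_rois=1, n_hc=3000, n_ad=0, seed=43)
    table = nb.generate_cohort(spec)
    train, test = nb.stratified_split(table, 2000 / 3000, seed=43)
    res = WarpedBLR.from_cohort(train, "roi-001").fit()
    z = res.zscore(test)[:1000]
    assert abs(z.mean()) < 0.05
    assert abs(z.var(ddof=1) - 1.0) < 0.1
    assert stats.kstest(z, "norm").pvalue > 0.01


def test_centiles_median_and_symmetry(gaussian_cohort):
    res = WarpedBLR.from_cohort(gaussian_cohort, "roi-001").fit()
    ages = np.linspace(46, 81, 25)
    curves = res.centiles(ages, quantiles=(0.05, 0.5, 0.95))
    # a ~= 0 for Gaussian data: the median curve is the point prediction
    grid = curves[["age"]].assign(sex="F", site="site-01")
    pred = res.predict(grid)
    np.testing.assert_allclose(curves["q0.5"], pred.point_prediction,
                               atol=5e-3 * res.model.y_sd + 1e-8)
    assert (curves["q0.05"] < curves["q0.95"]).all()


def test_centiles_gaussian_closed_form():
    """Identity warp, fixed hyperparameters: centiles are mu +/- 1.6449 sd."""
    rng = np.random.default_rng(9)
    n = 500
    from conftest import make_table

    table = make_table(n, seed=9)
    table["roi"] = 2.0 + 0.3 * rng.normal(size=n)
    model = WarpedBLR.from_cohort(table, "roi")
    res = NormativeModelResults(model, (5.0, 0.0, 0.0, 0.0))  # tight prior
    ages = np.linspace(50, 75, 10)
    curves = res.centiles(ages, quantiles=(0.05, 0.5, 0.95))
    grid = curves[["age"]].assign(sex="F", site="site-01")
    pred = res.predict(grid)
    half = stats.norm.ppf(0.95) * pred.total_sd * res.model.y_sd
    np.testing.assert_allclose(curves["q0.95"] - curves["q0.5"], half,
                               atol=1e-8)
    np.testing.assert_allclose(curves["q0.5"] - curves["q0.05"], half,
                               atol=1e-8)


def test_centile_curves_never_cross(small_models):
    res = small_models["roi-002"]
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    curves = res.centiles(np.linspace(45, 82, 50), quantiles=qs)
    for lo, hi in zip(qs, qs[1:]):
        assert (curves[f"q{lo:g}"] < curves[f"q{hi:g}"]).all()


def test_centiles_reject_invalid_quantiles(small_models):
    with pytest.raises(ValueError):
        small_models["roi-001"].centiles([60.0], quantiles=(0.0, 0.5))
    with pytest.raises(ValueError):
        small_models["roi-001"].centiles([60.0], quantiles=(1.2,))


def test_serialization_roundtrip(tmp_path, small_models, small_pool):
    res = small_models["roi-003"]
    path = tmp_path / "roi-003.json"
    res.save(path)
    loaded = NormativeModelResults.load(path)
    probe = small_pool.head(25)
    p0, p1 = res.predict(probe), loaded.predict(probe)
    np.testing.assert_allclose(p0.mu_warped, p1.mu_warped, atol=1e-10)
    np.testing.assert_allclose(p0.total_sd, p1.total_sd, atol=1e-10)
    np.testing.assert_allclose(res.zscore(probe), loaded.zscore(probe),
                               atol=1e-10)


def test_summary_reports_key_quantities(small_models):
    text = small_models["roi-001"].summary()
    for token in ("alpha", "beta", "warp skew", "converged", "roi-001"):
        assert token in text
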