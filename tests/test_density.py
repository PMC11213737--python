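"""GMM and normalizing-flow density models: oracles, analytic limits, EM
properties, invertibility, and anomaly-score contracts."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import lungood as lg
from lungood.density import (FlowModel, fit_flow, fit_gmm, flow_log_prob,
                             gmm_log_prob, init_flow, save_density,
                             load_density, select_k_bic)
from lungood.types import Representation


def _random_gmm(rng, k, d):
    w = rng.dirichlet(np.ones(k))
    means = rng.normal(0, 3, (k, d))
    covs = rng.uniform(0.3, 2.0, (k, d))
    return lg.GMMModel(weights=w, means=means, covariances=covs,
                       covariance_type="diag")


def _brute_log_prob(model, z):
    dens = 0.0
    for w, mu, var in zip(model.weights, model.means, model.covariances):
        dens += w * multivariate_normal.pdf(z, mean=mu, cov=np.diag(var))
    return np.log(dens)


def test_gmm_log_prob_matches_brute_force_sum(rng):
    for _ in range(20):
        k = int(rng.integers(1, 5))
        d = int(rng.integers(1, 6))
        model = _random_gmm(rng, k, d)
        z = rng.normal(0, 3, d)
        assert gmm_log_prob(model, z) == pytest.approx(
            _brute_log_prob(model, z), abs=1e-10)


def test_standard_normal_log_density_at_origin():
    model = lg.GMMModel(weights=np.ones(1), means=np.zeros((1, 2)),
                        covariances=np.ones((1, 2)), covariance_type="diag")
    assert gmm_log_prob(model, np.zeros(2)) == pytest.approx(
        -np.log(2 * np.pi), abs=1e-12)


def test_log_prob_decreases_along_ray_from_mean(rng):
    model = _random_gmm(rng, 3, 4)
    nearest = model.means[0]
    direction = rng.normal(size=4)
    direction /= np.linalg.norm(direction)
    lps = [gmm_log_prob(model, nearest + t * direction)
           for t in np.linspace(10, 40, 8)]
    assert all(a > b for a, b in zip(lps, lps[1:]))


def test_k1_fit_recovers_sample_mle(rng):
    Z = rng.normal(2.0, 1.5, size=(200, 3))
    model = fit_gmm(Z, 1, seed=0)
    np.testing.assert_allclose(model.means[0], Z.mean(axis=0), atol=1e-8)
    np.testing.assert_allclose(model.covariances[0], Z.var(axis=0), atol=1e-8)


@pytest.mark.parametrize("seed", range(10))
def test_two_component_parameter_recovery(seed):
    rng = np.random.default_rng(seed)
    Z = np.vstack([rng.normal((-5, 0), 1.0, (250, 2)),
                   rng.normal((5, 0), 1.0, (250, 2))])
    model = fit_gmm(Z, 2, seed=seed)
    got = model.means[np.argsort(model.means[:, 0])]
    truth = np.array([[-5.0, 0.0], [5.0, 0.0]])
    assert np.abs(got - truth).max() < 0.3


def test_em_trace_monotone_nondecreasing(rng):
    Z = rng.normal(size=(120, 3)) + rng.integers(0, 2, (120, 1)) * 4.0
    model = fit_gmm(Z, 2, n_init=1, seed=1)
    tr = np.asarray(model.log_likelihood_trace)
    assert np.all(np.diff(tr) >= -1e-7 * np.maximum(np.abs(tr[:-1]), 1.0))


def test_fit_matches_sklearn_cross_check(rng):
    """Independent EM implementation (scikit-learn) agrees on the fitted
    density up to small optimization differences."""
    from sklearn.mixture import GaussianMixture

    Z = np.vstack([rng.normal((-4, 1), 1.0, (150, 2)),
                   rng.normal((4, -1), 1.0, (150, 2))])
    ours = fit_gmm(Z, 2, seed=0)
    ref = GaussianMixture(2, covariance_type="diag", n_init=3,
                          random_state=0).fit(Z)
    x = rng.normal(0, 3, (50, 2))
    np.testing.assert_allclose(gmm_log_prob(ours, x), ref.score_samples(x),
                               atol=0.1)


def test_fit_error_contracts(rng):
    Z = rng.normal(size=(10, 2))
    with pytest.raises(ValueError):
        fit_gmm(Z, 0)
    with pytest.raises(ValueError):
        fit_gmm(Z, 10)
    with pytest.raises(ValueError, match="degenerate"):
        fit_gmm(np.ones((20, 2)), 2)
    with pytest.raises(ValueError, match="dimension"):
        gmm_log_prob(fit_gmm(Z, 1), np.zeros(5))


def test_bic_selects_reasonable_k(rng):
    Z = np.vstack([rng.normal((-6, 0), 1.0, (200, 2)),
                   rng.normal((6, 0), 1.0, (200, 2))])
    model = select_k_bic(Z, k_max=5, seed=0)
    assert model.n_components == 2


def test_seed_reproducibility(rng):
    Z = rng.normal(size=(100, 3))
    a = fit_gmm(Z, 2, seed=3)
    b = fit_gmm(Z, 2, seed=3)
    np.testing.assert_array_equal(a.means, b.means)
    np.testing.assert_array_equal(a.covariances, b.covariances)


# --- normalizing flow ------------------------------------------------------

def test_identity_initialized_flow_reproduces_base_density(rng):
    flow = init_flow(2, seed=0)
    assert flow_log_prob(flow, np.zeros(2)) == pytest.approx(
        -np.log(2 * np.pi), abs=1e-12)
    z = rng.normal(size=(20, 2))
    expected = -0.5 * np.sum(z**2, axis=1) - np.log(2 * np.pi)
    np.testing.assert_allclose(flow_log_prob(flow, z), expected, atol=1e-12)


def test_flow_forward_inverse_roundtrip(rng):
    Z = rng.normal(size=(300, 3)) * 2 + 1
    flow = fit_flow(Z, n_layers=4, hidden_units=16, epochs=30, seed=0)
    x = rng.normal(size=(100, 3)) * 2
    back = flow.inverse(flow.forward(x))
    assert np.max(np.abs(back - x)) < 1e-5


def test_flow_logdet_matches_numeric_jacobian(rng):
    Z = rng.normal(size=(200, 3))
    flow = fit_flow(Z, n_layers=4, hidden_units=8, epochs=40, seed=2)
    for _ in range(5):
        z = rng.normal(size=3)
        eps = 1e-6
        J = np.zeros((3, 3))
        for j in range(3):
            dz = np.zeros(3)
            dz[j] = eps
            J[:, j] = (flow.forward(z + dz)[0] - flow.forward(z - dz)[0]) / (2 * eps)
        _, numeric = np.linalg.slogdet(J)
        u = flow.forward(z)[0]
        base = -0.5 * np.sum(u**2) - 1.5 * np.log(2 * np.pi)
        analytic = flow_log_prob(flow, z) - base
        assert analytic == pytest.approx(numeric, abs=1e-4)


def test_flow_fit_approaches_gaussian_entropy(rng):
    """On standard-normal data the achievable mean log-likelihood is the
    negative differential entropy -(D/2)(log 2 pi + 1)."""
    D = 4
    Z = rng.normal(size=(500, D))
    flow = fit_flow(Z, epochs=150, seed=1)
    target = -0.5 * D * (np.log(2 * np.pi) + 1.0)
    assert np.mean(flow_log_prob(flow, Z)) == pytest.approx(target, abs=0.5)


def test_flow_density_integrates_to_one_2d(rng):
    Z = rng.normal(size=(400, 2))
    flow = fit_flow(Z, n_layers=4, hidden_units=16, epochs=80, seed=3)
    g = np.linspace(-6, 6, 121)
    xx, yy = np.meshgrid(g, g)
    pts = np.stack([xx.reshape(-1), yy.reshape(-1)], axis=1)
    dens = np.exp(flow_log_prob(flow, pts))
    integral = dens.sum() * (g[1] - g[0]) ** 2
    assert integral == pytest.approx(1.0, abs=0.05)


def test_flow_rejects_one_dimensional_input():
    with pytest.raises(ValueError, match="dim >= 2"):
        init_flow(1)


# --- anomaly scores --------------------------------------------------------

def test_anomaly_score_sign_contract(rng):
    model = _random_gmm(rng, 2, 3)
    for _ in range(10):
        z = rng.normal(size=3)
        rep = Representation(z=z, subject_id="s", origin=(0, 0, 0))
        sc = lg.anomaly_score(model, rep)
        assert sc.s == pytest.approx(-gmm_log_prob(model, z))


def test_score_is_minimal_at_single_component_mean():
    model = lg.GMMModel(weights=np.ones(1), means=np.full((1, 2), 1.5),
                        covariances=np.ones((1, 2)), covariance_type="diag")
    rng = np.random.default_rng(0)
    at_mean = -gmm_log_prob(model, model.means[0])
    for _ in range(20):
        z = model.means[0] + rng.normal(size=2)
        assert -gmm_log_prob(model, z) >= at_mean


def test_density_serialization_roundtrip(tmp_path, rng):
    Z = rng.normal(size=(100, 3))
    x = rng.normal(size=(10, 3))
    gmm = fit_gmm(Z, 2, seed=0)
    save_density(gmm, tmp_path / "g.npz")
    np.testing.assert_allclose(gmm_log_prob(load_density(tmp_path / "g.npz"), x),
                               gmm_log_prob(gmm, x), atol=1e-12)
    flow = fit_flow(Z, n_layers=2, hidden_units=8, epochs=5, seed=0)
    save_density(flow, tmp_path / "f.npz")
    loaded = load_density(tmp_path / "f.npz")
    assert isinstance(loaded, FlowModel)
    np.testing.assert_allclose(flow_log_prob(loaded, x),
                               flow_log_prob(flow, x), atol=1e-12)
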