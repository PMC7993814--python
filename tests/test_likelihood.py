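import numpy as np
import pytest
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from hopitx.data import HopitParams, SurveyDataset
from hopitx.likelihood import QmcDraws, halton_points, individual_loglik, total_loglik


class TestHaltonPoints:
    def test_deterministic(self):
        a = halton_points(500)
        b = halton_points(500)
        assert np.array_equal(a.uniforms, b.uniforms)

    def test_open_unit_interval(self):
        d = halton_points(2000)
        assert d.uniforms.min() > 0 and d.uniforms.max() < 1

    def test_normal_moments_at_large_R(self):
        d = halton_points(10000)
        z = ndtri(d.uniforms)
        assert np.all(np.abs(z.mean(axis=0)) < 0.02)
        assert np.all(np.abs(z.std(axis=0) - 1) < 0.02)

    def test_skip_and_leap_change_points(self):
        base = halton_points(100)
        assert not np.array_equal(base.uniforms, halton_points(100, skip=0).uniforms)
        assert not np.array_equal(base.uniforms, halton_points(100, leap=7).uniforms)

    def test_invalid_R(self):
        with pytest.raises(ValueError):
            halton_points(0)


class TestKernelAgainstReference:
    """The jitted kernel and the numpy reference are one estimator."""

    @pytest.mark.parametrize("alpha", [0.0, 0.05, -0.1])
    def test_paths_agree_to_machine_precision(self, alpha, small_sim):
        data = small_sim.dataset
        params = HopitParams(
            beta=small_sim.params.beta * 0.9,
            gamma=small_sim.params.gamma * 1.1,
            theta=small_sim.params.theta + 0.1,
            sigma_u=0.35,
            sigma_v=0.8,
            alpha=alpha,
        )
        draws = halton_points(128)
        fast = total_loglik(params, data, draws, use_kernel=True)
        ref = total_loglik(params, data, draws, use_kernel=False)
        np.testing.assert_allclose(fast.per_respondent, ref.per_respondent, rtol=1e-10)


def _op_cell_prob(y, xb, tau):
    aug = np.concatenate([[-np.inf], tau, [np.inf]])
    return ndtr(aug[y] - xb) - ndtr(aug[y - 1] - xb)


class TestDegenerateNesting:
    def test_no_vignettes_tiny_sigma_u_is_ordered_probit(self):
        # J = 0 and sigma_u -> 0: log l_i is the ordered-probit cell log-prob
        X = np.array([[0.4, -1.2], [1.0, 0.3], [-0.5, 0.8]])
        Z = np.hstack([np.ones((3, 1)), X])
        y = np.array([1, 2, 3])
        data = SurveyDataset(y=y, V=np.empty((3, 0), dtype=int), X=X, Z=Z, K=3)
        beta = np.array([0.6, -0.4])
        gamma = np.array([[-0.2, 0.0, 0.0], [0.1, 0.0, 0.0]])
        params = HopitParams(
            beta=beta, gamma=gamma, theta=np.empty(0), sigma_u=1e-12, sigma_v=1.0
        )
        res = total_loglik(params, data, halton_points(64))
        xb = X @ beta
        tau = np.array([-0.2, -0.2 + np.exp(0.1)])
        expected = np.log(_op_cell_prob(y, xb, tau))
        np.testing.assert_allclose(res.per_respondent, expected, rtol=1e-9)

    def test_alpha_zero_matches_standard_hopit_oracle(self, small_sim):
        # independent standard-HOPIT computation: eps integrated out
        # analytically, only u simulated — compare with the importance
        # sampled path at alpha = 0 using the same draws
        data = small_sim.dataset
        p0 = small_sim.params
        params = HopitParams(
            beta=p0.beta, gamma=p0.gamma, theta=p0.theta,
            sigma_u=p0.sigma_u, sigma_v=p0.sigma_v, alpha=0.0,
        )
        draws = halton_points(256)
        got = total_loglik(params, data, draws).per_respondent

        u = ndtri(draws.uniforms[:, 0])
        xb = data.X @ params.beta
        lin = data.Z @ params.gamma.T
        t1 = lin[:, 0][:, None] + params.sigma_u * u[None, :]
        t2 = t1 + np.exp(lin[:, 1])[:, None]
        aug = np.stack(
            [np.full_like(t1, -np.inf), t1, t2, np.full_like(t1, np.inf)], axis=2
        )
        rows = np.arange(data.n)

        def cell(hi, lo):
            # tail-stable Phi(hi) - Phi(lo): difference of survival
            # functions in the upper tail, of CDFs in the lower tail
            sf_form = np.where(
                np.isneginf(lo), 1.0, norm.sf(np.where(np.isneginf(lo), 0.0, lo))
            ) - np.where(np.isposinf(hi), 0.0, norm.sf(np.where(np.isposinf(hi), 0.0, hi)))
            cdf_form = np.where(
                np.isposinf(hi), 1.0, norm.cdf(np.where(np.isposinf(hi), 0.0, hi))
            ) - np.where(np.isneginf(lo), 0.0, norm.cdf(np.where(np.isneginf(lo), 0.0, lo)))
            with np.errstate(invalid="ignore"):
                use_sf = lo > -hi
            return np.where(use_sf, sf_form, cdf_form)

        w = cell(aug[rows, :, data.y] - xb[:, None],
                 aug[rows, :, data.y - 1] - xb[:, None])
        lik = w
        for j in range(data.J):
            pj = cell(
                (aug[rows, :, data.V[:, j]] - params.theta[j]) / params.sigma_v,
                (aug[rows, :, data.V[:, j] - 1] - params.theta[j]) / params.sigma_v,
            )
            lik = lik * pj
        with np.errstate(divide="ignore"):
            expected = np.log(lik.mean(axis=1))
        # deep-tail respondents (cell mass under ~1e-90) are dominated by
        # underflow order-of-operations, not by the estimator itself
        mask = expected > -200
        assert mask.sum() > 0.9 * data.n
        np.testing.assert_allclose(got[mask], expected[mask], atol=1e-8)


def _dense_grid_loglik(params, y, V, x, z, n_u=160, n_e=160):
    """Brute-force dense integration of the double integral.

    Outer: Gauss-Hermite over the cut-point shift u (smooth integrand).
    Inner: the self-report indicator truncates eps to [a, b]; change of
    variable t = Phi(eps) turns that into a smooth integral over
    [Phi(a), Phi(b)], handled by Gauss-Legendre.  Entirely independent
    of the package's importance-sampling path.
    """
    from numpy.polynomial.hermite_e import hermegauss
    from numpy.polynomial.legendre import leggauss

    u_nodes, u_w = hermegauss(n_u)
    u_w = u_w / np.sqrt(2 * np.pi)
    t_nodes, t_w = leggauss(n_e)  # on [-1, 1]
    xb = float(x @ params.beta)
    lin = z @ params.gamma.T
    total = 0.0
    for u, wu in zip(u_nodes, u_w):
        tau = np.empty(params.K - 1)
        tau[0] = lin[0] + params.sigma_u * u
        for k in range(1, params.K - 1):
            tau[k] = tau[k - 1] + np.exp(lin[k])
        aug = np.concatenate([[-np.inf], tau, [np.inf]])
        ta = norm.cdf(aug[y - 1] - xb)
        tb = norm.cdf(aug[y] - xb)
        if tb <= ta:
            continue
        t = 0.5 * (tb - ta) * (t_nodes + 1) + ta
        eps = norm.ppf(np.clip(t, 1e-300, 1 - 1e-16))
        ystar = xb + eps
        term = np.ones_like(ystar)
        for j in range(len(params.theta)):
            s = params.sigma_v * np.exp(
                params.alpha * (ystar - params.theta[j]) ** 2
            )
            kj = V[j]
            term *= norm.cdf((aug[kj] - params.theta[j]) / s) - norm.cdf(
                (aug[kj - 1] - params.theta[j]) / s
            )
        inner = 0.5 * (tb - ta) * (t_w @ term)
        total += wu * inner
    return np.log(total)


@pytest.fixture(scope="module")
def toy_five():
    rng = np.random.default_rng(3)
    X = rng.normal(scale=0.7, size=(5, 2))
    Z = np.hstack([np.ones((5, 1)), X])
    y = np.array([1, 2, 3, 2, 1])
    V = np.array([[1], [2], [3], [1], [3]])
    data = SurveyDataset(y=y, V=V, X=X, Z=Z, K=3)
    params = HopitParams(
        beta=np.array([0.9, -0.6]),
        gamma=np.array([[-0.3, 0.4, -0.1], [0.2, 0.0, 0.3]]),
        theta=np.array([0.4]),
        sigma_u=0.4,
        sigma_v=0.9,
        alpha=0.05,
    )
    return data, params


class TestImportanceSamplingOracle:
    def test_unbiased_against_tensor_grid(self, toy_five):
        # QMC importance-sampled log l_i vs dense Gauss-Hermite grid
        data, params = toy_five
        draws = halton_points(8192)
        got = total_loglik(params, data, draws).per_respondent
        for i in range(data.n):
            exact = _dense_grid_loglik(
                params, data.y[i], data.V[i], data.X[i], data.Z[i]
            )
            assert got[i] == pytest.approx(exact, abs=1e-4)

    def test_total_probability_over_all_patterns(self, toy_five):
        # sum of exact l over the K^(J+1) response patterns = 1
        data, params = toy_five
        total = 0.0
        for y in (1, 2, 3):
            for v in (1, 2, 3):
                total += np.exp(
                    _dense_grid_loglik(
                        params, y, np.array([v]), data.X[0], data.Z[0]
                    )
                )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_simulated_total_probability_over_all_patterns(self, toy_five):
        # same conservation law for the QMC importance-sampled estimator
        data, params = toy_five
        draws = halton_points(4096)
        total = 0.0
        for y in (1, 2, 3):
            for v in (1, 2, 3):
                d1 = SurveyDataset(
                    y=np.array([y]), V=np.array([[v]]),
                    X=data.X[:1], Z=data.Z[:1], K=3,
                )
                total += np.exp(total_loglik(params, d1, draws).total)
        assert total == pytest.approx(1.0, abs=1e-4)


class TestTotalLoglik:
    def test_singleton_equals_individual(self, toy_five):
        data, params = toy_five
        draws = halton_points(64)
        d1 = SurveyDataset(y=data.y[:1], V=data.V[:1], X=data.X[:1], Z=data.Z[:1], K=3)
        assert total_loglik(params, d1, draws).total == pytest.approx(
            individual_loglik(params, data, 0, draws), abs=1e-12
        )

    def test_row_permutation_invariance(self, small_sim):
        data = small_sim.dataset
        params = small_sim.params
        draws = halton_points(64)
        base = total_loglik(params, data, draws)
        perm = np.random.default_rng(1).permutation(data.n)
        shuffled = SurveyDataset(
            y=data.y[perm], V=data.V[perm], X=data.X[perm], Z=data.Z[perm], K=data.K
        )
        assert total_loglik(params, shuffled, draws).total == pytest.approx(
            base.total, abs=1e-8
        )
        assert base.total == pytest.approx(base.per_respondent.sum(), abs=1e-10)

    def test_vignette_column_permutation_with_theta(self, small_sim):
        data = small_sim.dataset
        params = small_sim.params
        draws = halton_points(64)
        base = total_loglik(params, data, draws).total
        order = [2, 0, 1]
        permuted = SurveyDataset(
            y=data.y, V=data.V[:, order], X=data.X, Z=data.Z, K=data.K
        )
        p2 = HopitParams(
            beta=params.beta, gamma=params.gamma, theta=params.theta[order],
            sigma_u=params.sigma_u, sigma_v=params.sigma_v, alpha=params.alpha,
        )
        assert total_loglik(p2, permuted, draws).total == pytest.approx(base, abs=1e-10)

    def test_draw_count_convergence(self, small_sim):
        data = small_sim.dataset
        params = small_sim.params
        totals = {R: total_loglik(params, data, halton_points(R)).total
                  for R in (50, 200, 800, 3200)}
        gap_small = abs(totals[50] - totals[200])
        gap_large = abs(totals[800] - totals[3200])
        assert gap_large < gap_small
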