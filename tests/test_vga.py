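import numpy as np
import pytest
from scipy import integrate, optimize, stats

from mvplnmix.exceptions import ValidationError
from mvplnmix.model_core import ComponentParams, CountTensor, MixtureParams, OffsetMatrix
from mvplnmix.simulate import build_benchmark_design, random_spd, simulate_mvpln_mixture
from mvplnmix.selection import adjusted_rand_index
from mvplnmix.vga import (
    FitConfig,
    VariationalEntry,
    VariationalState,
    elbo_observation,
    fit_vga,
    init_kmeans,
    mstep,
    responsibilities_from_elbo,
    update_Delta,
    update_kappa,
    update_xi,
)


def _scalar_entry(xi=0.3, De=0.5, ka=0.8):
    return VariationalEntry(np.array([[xi]]), np.array([[De]]), np.array([[ka]]))


def _quad_elbo(Y, s, xi, v, M, sig2):
    """Independent 1-d quadrature for E_q[log joint] + entropy."""
    sd = np.sqrt(v)

    def integrand(th):
        q = stats.norm.pdf(th, xi, sd)
        logj = (stats.poisson.logpmf(Y, np.exp(th) * s)
                + stats.norm.logpdf(th, M, np.sqrt(sig2)))
        return q * (logj - stats.norm.logpdf(th, xi, sd))

    val, _ = integrate.quad(integrand, xi - 12 * sd, xi + 12 * sd)
    return val


def _rand_instance(rng, r=2, p=3):
    comp = ComponentParams(M=rng.normal(1.0, 0.5, (r, p)),
                           Phi=random_spd(r, rng, eig_range=(0.5, 1.5)),
                           Omega=random_spd(p, rng, eig_range=(0.3, 0.8)))
    Y = rng.poisson(5.0, (r, p))
    off = OffsetMatrix(rng.uniform(0.5, 2.0, (r, p)))
    entry = VariationalEntry(
        xi=rng.normal(1.0, 0.5, (r, p)),
        Delta=random_spd(r, rng, eig_range=(0.1, 0.5)),
        kappa=random_spd(p, rng, eig_range=(0.1, 0.5)),
    )
    return Y, off, entry, comp


class TestElboObservation:
    def test_quadrature_identity_1x1(self, scalar_component, unit_offsets):
        entry = _scalar_entry()
        impl = elbo_observation([[1]], unit_offsets, entry, scalar_component)
        oracle = _quad_elbo(1, 1.0, 0.3, 0.5 * 0.8, 0.2, 1.2 * 0.9)
        assert impl == pytest.approx(oracle, abs=1e-6)

    def test_kronecker_scale_invariance(self, rng):
        Y, off, entry, comp = _rand_instance(rng)
        base = elbo_observation(Y, off, entry, comp)
        for c in (0.1, 3.7):
            scaled = VariationalEntry(entry.xi, c * entry.Delta, entry.kappa / c)
            assert elbo_observation(Y, off, scaled, comp) == pytest.approx(base, rel=1e-12)

    def test_lower_bound_property(self, scalar_component, unit_offsets):
        sig2 = 1.2 * 0.9
        marg, _ = integrate.quad(
            lambda th: np.exp(stats.poisson.logpmf(2, np.exp(th)))
            * stats.norm.pdf(th, 0.2, np.sqrt(sig2)), -15, 15)
        for xi in (-1.0, 0.0, 0.8):
            for v in (0.1, 0.5, 2.0):
                entry = _scalar_entry(xi, v, 1.0)
                F = elbo_observation([[2]], unit_offsets, entry, scalar_component)
                assert F <= np.log(marg) + 1e-12


def _numeric_grad_sym(f, A, eps=1e-6):
    """Numeric gradient of f over symmetric perturbations of A."""
    d = A.shape[0]
    G = np.zeros_like(A)
    for i in range(d):
        for j in range(i, d):
            E = np.zeros_like(A)
            E[i, j] = E[j, i] = 1.0 if i != j else 1.0
            G[i, j] = G[j, i] = (f(A + eps * E) - f(A - eps * E)) / (2 * eps)
    return G


class TestUpdateDelta:
    def test_stationary_gradient(self, rng):
        Y, off, entry, comp = _rand_instance(rng)
        De = entry.Delta
        for _ in range(200):
            new = update_Delta(VariationalEntry(entry.xi, De, entry.kappa), Y, off, comp)
            if np.max(np.abs(new - De)) < 1e-12:
                break
            De = new

        def f(A):
            return elbo_observation(Y, off, VariationalEntry(entry.xi, A, entry.kappa), comp)

        G = _numeric_grad_sym(f, De)
        assert np.max(np.abs(G)) < 1e-5

    def test_scalar_matches_1d_maximization(self, scalar_component, unit_offsets):
        entry = _scalar_entry(0.1, 0.3, 0.7)
        De = entry.Delta
        for _ in range(200):
            new = update_Delta(VariationalEntry(entry.xi, De, entry.kappa),
                               [[3]], unit_offsets, scalar_component)
            if abs(new[0, 0] - De[0, 0]) < 1e-14:
                break
            De = new
        res = optimize.minimize_scalar(
            lambda ld: -elbo_observation([[3]], unit_offsets,
                                         VariationalEntry(entry.xi, np.array([[np.exp(ld)]]),
                                                          entry.kappa),
                                         scalar_component),
            bounds=(-8, 4), method="bounded",
            options={"xatol": 1e-12})
        assert De[0, 0] == pytest.approx(np.exp(res.x), abs=1e-6)

    def test_spd_output(self, rng):
        for _ in range(5):
            Y, off, entry, comp = _rand_instance(rng)
            out = update_Delta(entry, Y, off, comp)
            assert np.linalg.eigvalsh(out)[0] > 0
            np.testing.assert_allclose(out, out.T)


class TestUpdateKappa:
    def test_stationary_gradient(self, rng):
        Y, off, entry, comp = _rand_instance(rng)
        ka = entry.kappa
        for _ in range(200):
            new = update_kappa(VariationalEntry(entry.xi, entry.Delta, ka), Y, off, comp)
            if np.max(np.abs(new - ka)) < 1e-12:
                break
            ka = new

        def f(A):
            return elbo_observation(Y, off, VariationalEntry(entry.xi, entry.Delta, A), comp)

        G = _numeric_grad_sym(f, ka)
        assert np.max(np.abs(G)) < 1e-5

    def test_p1_scalar_case(self, rng):
        comp = ComponentParams(M=[[0.5], [0.2]], Phi=random_spd(2, rng),
                               Omega=[[0.8]])
        off = OffsetMatrix(np.ones((2, 1)))
        entry = VariationalEntry(np.array([[0.1], [0.4]]),
                                 random_spd(2, rng, eig_range=(0.2, 0.5)),
                                 np.array([[0.3]]))
        Y = np.array([[2], [5]])
        ka = entry.kappa
        for _ in range(200):
            new = update_kappa(VariationalEntry(entry.xi, entry.Delta, ka), Y, off, comp)
            if abs(new[0, 0] - ka[0, 0]) < 1e-14:
                break
            ka = new
        res = optimize.minimize_scalar(
            lambda lk: -elbo_observation(Y, off,
                                         VariationalEntry(entry.xi, entry.Delta,
                                                          np.array([[np.exp(lk)]])), comp),
            bounds=(-8, 4), method="bounded", options={"xatol": 1e-12})
        assert ka[0, 0] == pytest.approx(np.exp(res.x), abs=1e-6)

    def test_spd_output(self, rng):
        Y, off, entry, comp = _rand_instance(rng)
        out = update_kappa(entry, Y, off, comp)
        assert np.linalg.eigvalsh(out)[0] > 0


class TestUpdateXi:
    def _converge_xi(self, entry, Y, off, comp, iters=100):
        xi = entry.xi
        for _ in range(iters):
            new = update_xi(VariationalEntry(xi, entry.Delta, entry.kappa), Y, off, comp)
            if np.max(np.abs(new - xi)) < 1e-13:
                break
            xi = new
        return xi

    def test_numeric_gradient_at_convergence(self, rng):
        Y, off, entry, comp = _rand_instance(rng)
        xi = self._converge_xi(entry, Y, off, comp)

        def f(x):
            return elbo_observation(Y, off, VariationalEntry(x, entry.Delta, entry.kappa), comp)

        eps = 1e-6
        for i in range(xi.shape[0]):
            for k in range(xi.shape[1]):
                E = np.zeros_like(xi)
                E[i, k] = eps
                g = (f(xi + E) - f(xi - E)) / (2 * eps)
                assert abs(g) < 1e-5

    def test_poisson_mle_limit(self):
        Y = np.array([[200.0, 350.0], [150.0, 500.0]])
        off = OffsetMatrix(np.full((2, 2), 1.3))
        comp = ComponentParams(M=np.zeros((2, 2)), Phi=10 * np.eye(2),
                               Omega=10 * np.eye(2))
        entry = VariationalEntry(np.log(Y / off.s), 1e-5 * np.eye(2), 1e-5 * np.eye(2))
        xi = self._converge_xi(entry, Y, off, comp)
        np.testing.assert_allclose(xi, np.log(Y / off.s), atol=1e-3)

    def test_zero_count_shrinkage(self, scalar_component, unit_offsets):
        comp = ComponentParams([[0.0]], [[1.0]], [[1.0]])
        entry = _scalar_entry(0.0, 0.2, 0.2)
        xi = self._converge_xi(entry, np.array([[0]]), unit_offsets, comp)
        assert xi[0, 0] < 0
        res = optimize.minimize_scalar(
            lambda x: -elbo_observation([[0]], unit_offsets,
                                        VariationalEntry(np.array([[x]]), entry.Delta,
                                                         entry.kappa), comp),
            bounds=(-10, 5), method="bounded", options={"xatol": 1e-12})
        assert xi[0, 0] == pytest.approx(res.x, abs=1e-6)


class TestCoordinateMonotonicity:
    def test_updates_never_decrease_elbo(self, rng):
        for _ in range(10):
            Y, off, entry, comp = _rand_instance(rng)
            f0 = elbo_observation(Y, off, entry, comp)
            De = update_Delta(entry, Y, off, comp)
            assert elbo_observation(Y, off, VariationalEntry(entry.xi, De, entry.kappa),
                                    comp) >= f0 - 1e-8
            ka = update_kappa(entry, Y, off, comp)
            assert elbo_observation(Y, off, VariationalEntry(entry.xi, entry.Delta, ka),
                                    comp) >= f0 - 1e-8
            xi = update_xi(entry, Y, off, comp)
            assert elbo_observation(Y, off, VariationalEntry(xi, entry.Delta, entry.kappa),
                                    comp) >= f0 - 1e-8


class TestResponsibilities:
    def test_single_component(self):
        z = responsibilities_from_elbo([1.0], np.full((5, 1), -30.0))
        np.testing.assert_array_equal(z, np.ones((5, 1)))

    def test_symmetry(self):
        z = responsibilities_from_elbo([0.5, 0.5], np.full((3, 2), -1000.0))
        np.testing.assert_allclose(z, 0.5)

    def test_logistic_underflow_safety(self):
        z = responsibilities_from_elbo([0.5, 0.5], np.array([[-1000.0, -1001.0]]))
        np.testing.assert_allclose(z[0], [0.7310585786, 0.2689414214], atol=1e-9)

    def test_rows_sum_to_one(self, rng):
        z = responsibilities_from_elbo([0.2, 0.3, 0.5], rng.normal(-50, 20, (20, 3)))
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-12)

    def test_all_neginf_row_raises(self):
        with pytest.raises(ValidationError):
            responsibilities_from_elbo([0.5, 0.5], np.array([[-np.inf, -np.inf]]))


class TestMstep:
    def test_weighted_average_reduction(self, rng):
        N, r, p, G = 6, 2, 2, 2
        tensor = CountTensor(rng.poisson(5.0, (N, r, p)))
        off = OffsetMatrix.ones(r, p)
        state = VariationalState.initialize(tensor, off, G, var0=1e-10)
        xi_a = rng.standard_normal((r, p))
        xi_b = rng.standard_normal((r, p))
        state.xi[:3, 0] = xi_a
        state.xi[3:, 1] = xi_b
        z = np.zeros((N, G))
        z[:3, 0] = 1.0
        z[3:, 1] = 1.0
        params = mstep(tensor, off, z, state, None)
        np.testing.assert_allclose(params.components[0].M, xi_a, atol=1e-8)
        np.testing.assert_allclose(params.components[1].M, xi_b, atol=1e-8)
        np.testing.assert_allclose(params.pi, [0.5, 0.5])

    def test_rank_deficient_triggers_jitter_warning(self, rng):
        N, r, p = 2, 2, 2
        tensor = CountTensor(rng.poisson(5.0, (N, r, p)))
        off = OffsetMatrix.ones(r, p)
        state = VariationalState.initialize(tensor, off, 1, var0=0.0)
        # two xi differing only along one row direction -> rank-1 quadratic term
        state.xi[0, 0] = np.array([[1.0, 1.0], [0.0, 0.0]])
        state.xi[1, 0] = np.array([[-1.0, -1.0], [0.0, 0.0]])
        z = np.ones((N, 1))
        with pytest.warns(UserWarning, match="jitter"):
            mstep(tensor, off, z, state, None)

    def test_parameter_recovery_oracle(self, rng):
        N, r, p = 5000, 2, 3
        comps = [
            ComponentParams(M=rng.normal(3.0, 1.0, (r, p)),
                            Phi=random_spd(r, rng, eig_range=(0.5, 1.0)),
                            Omega=random_spd(p, rng, eig_range=(0.2, 0.5)))
            for _ in range(2)
        ]
        labels = rng.integers(0, 2, N)
        thetas = np.empty((N, r, p))
        for g, c in enumerate(comps):
            idx = labels == g
            A = np.linalg.cholesky(c.Phi)
            B = np.linalg.cholesky(c.Omega).T
            thetas[idx] = c.M + A @ rng.standard_normal((idx.sum(), r, p)) @ B
        tensor = CountTensor(rng.poisson(np.exp(np.clip(thetas, None, 10))))
        off = OffsetMatrix.ones(r, p)
        state = VariationalState.initialize(tensor, off, 2, var0=1e-10)
        for g in range(2):
            state.xi[:, g] = thetas
        z = np.zeros((N, 2))
        z[np.arange(N), labels] = 1.0
        params = mstep(tensor, off, z, state, None)
        for g, c in enumerate(comps):
            np.testing.assert_allclose(params.components[g].M, c.M, atol=0.1)
            est = np.kron(params.components[g].Phi, params.components[g].Omega)
            true = np.kron(c.Phi, c.Omega)
            rel = np.linalg.norm(est - true) / np.linalg.norm(true)
            assert rel < 0.1


class TestInitKmeans:
    def test_separable_clouds(self, rng):
        low = rng.poisson(5.0, (30, 1, 2))
        high = rng.poisson(500.0, (30, 1, 2))
        tensor = CountTensor(np.concatenate([low, high]))
        z = init_kmeans(tensor, 2, n_runs=10, seed=0)
        labels = z.argmax(axis=1)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_index(labels, truth) == 1.0

    def test_single_cluster(self, rng):
        tensor = CountTensor(rng.poisson(5.0, (10, 1, 2)))
        np.testing.assert_array_equal(init_kmeans(tensor, 1), np.ones((10, 1)))

    def test_deterministic(self, sim2_small):
        a = init_kmeans(sim2_small.tensor, 2, n_runs=5, seed=7)
        b = init_kmeans(sim2_small.tensor, 2, n_runs=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_few_units(self, rng):
        tensor = CountTensor(rng.poisson(5.0, (3, 1, 1)))
        with pytest.raises(ValidationError):
            init_kmeans(tensor, 5)


class TestFitVga:
    def test_sim2_perfect_ari(self, sim2_small):
        res = fit_vga(sim2_small.tensor, sim2_small.offsets, 2, FitConfig(seed=1))
        assert adjusted_rand_index(res.map_labels, sim2_small.labels) == 1.0
        assert res.converged

    def test_pi_recovery(self, sim2_small):
        res = fit_vga(sim2_small.tensor, sim2_small.offsets, 2, FitConfig(seed=1))
        assert abs(res.params.pi.max() - 0.79) < 0.08

    def test_g1_monotone(self, sim1_small):
        res = fit_vga(sim1_small.tensor, sim1_small.offsets, 1, FitConfig(seed=1))
        np.testing.assert_allclose(res.params.pi, [1.0])
        assert np.all(res.responsibilities == 1.0)
        tr = res.elbo_trace
        assert np.all(np.diff(tr) >= -1e-6 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_elbo_trace_monotone(self, sim2_small):
        res = fit_vga(sim2_small.tensor, sim2_small.offsets, 2, FitConfig(seed=1))
        tr = res.elbo_trace
        assert np.all(np.diff(tr) >= -1e-6 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_result_sanity(self, sim2_small):
        res = fit_vga(sim2_small.tensor, sim2_small.offsets, 2, FitConfig(seed=1))
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.isfinite(res.responsibilities))
        assert np.all(np.isfinite(res.elbo_trace))
        np.testing.assert_array_equal(res.map_labels,
                                      res.responsibilities.argmax(axis=1) + 1)
        # identifiability normalization applied
        for c in res.params.components:
            assert c.Phi[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert res.K == 31  # (G-1) + G*r*p + G*(r(r+1)+p(p+1))/2 at G=2,r=2,p=3

    def test_deterministic(self, sim2_small):
        a = fit_vga(sim2_small.tensor, sim2_small.offsets, 2, FitConfig(seed=3))
        b = fit_vga(sim2_small.tensor, sim2_small.offsets, 2, FitConfig(seed=3))
        np.testing.assert_array_equal(a.responsibilities, b.responsibilities)
        np.testing.assert_array_equal(a.elbo_trace, b.elbo_trace)
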