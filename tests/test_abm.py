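import numpy as np
import pytest

from virowave.abm import (
    LatticeState,
    ensemble,
    movement_probabilities,
    simulate,
    step,
)
from virowave.core import (
    InitialCondition,
    Lattice,
    ModelParams,
    Plateau,
    StabilityError,
    make_initial_state,
)

from conftest import no_infection_ic


def uniform_state(U=0, I=0, v=0.0, n=21, delta=0.1, dimension=1):
    shape = (n,) * dimension
    return LatticeState(
        U=np.full(shape, U, dtype=np.int64),
        I=np.full(shape, I, dtype=np.int64),
        v=np.full(shape, float(v)),
        t=0.0,
        delta=delta,
        dimension=dimension,
    )


class TestStep:
    def test_no_infection_without_virus(self, params, rng):
        state = uniform_state(U=50, v=0.0)
        pk = params.replace(beta=0.0)
        for _ in range(20):
            state = step(state, pk, rng)
        assert (state.I == 0).all()

    def test_counts_stay_nonnegative(self, params, rng):
        state = uniform_state(U=90, I=30, v=1e4)
        for _ in range(50):
            state = step(state, params, rng)
            assert (state.U >= 0).all()
            assert (state.I >= 0).all()
            assert (state.v >= -1e-12).all()

    def test_conservation_without_events(self, params, rng):
        # movement off and demography off: totals are conserved exactly
        pk = params.replace(p=0.0, q=0.0, beta=0.0, D_U=0.0)
        state = uniform_state(U=40, I=10)
        for _ in range(10):
            state = step(state, pk, rng)
        assert state.U.sum() == 40 * 21
        assert state.I.sum() == 10 * 21

    def test_movement_alone_conserves(self, params, rng):
        pk = params.replace(p=0.0, q=0.0, beta=0.0)
        state = uniform_state(U=40, I=10)
        tot = state.U.sum() + state.I.sum()
        for _ in range(20):
            state = step(state, pk, rng)
        assert state.U.sum() + state.I.sum() == tot

    def test_viral_geometric_decay(self, params, rng):
        # uniform v with no infected cells decays exactly geometrically:
        # the Laplacian vanishes so v_{n+1} = (1 - tau*q_v) v_n at every site
        v0 = 1.0e4
        state = uniform_state(U=0, I=0, v=v0)
        n = 25
        for _ in range(n):
            state = step(state, params, rng)
        expected = v0 * (1 - params.tau * params.q_v) ** n
        np.testing.assert_allclose(state.v, expected, rtol=1e-12)

    def test_division_probability_low_density(self, params):
        # many independent single-occupancy sites; movement off so each site
        # is a Bernoulli(tau*p) division trial
        n = 200_000
        pk = params.replace(D_U=0.0, beta=0.0)
        state = uniform_state(U=1, n=n)
        rng = np.random.default_rng(7)
        new = step(state, pk, rng)
        births = int(new.U.sum()) - n
        expected = n * pk.tau * pk.p  # ~74.8
        assert births == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_probability_overflow_raises(self, params, rng):
        state = uniform_state(U=10, v=1e12)
        with pytest.raises(StabilityError):
            step(state, params, rng)

    def test_mean_field_increment(self, params):
        # single huge well-mixed site: one-step expected increments match the
        # non-spatial RHS to within sampling noise + O(tau)
        pk = params.replace(D_U=0.0, tau=1e-2, K=1e9)
        U0, I0, v0 = 10**8, 10**7, 1.0e9
        state = LatticeState(U=np.array([U0]), I=np.array([I0]),
                             v=np.array([float(v0)]), t=0.0,
                             delta=0.1, dimension=1)
        rng = np.random.default_rng(3)
        new = step(state, pk, rng)
        u, i = U0 / 0.1, I0 / 0.1
        rho = u + i
        du_rate = pk.p * u * (1 - rho / pk.K) - pk.beta * u * v0 / pk.K
        di_rate = pk.beta * u * v0 / pk.K - pk.q * i
        got_du = (new.U[0] - U0) / 0.1 / pk.tau
        got_di = (new.I[0] - I0) / 0.1 / pk.tau
        assert got_du == pytest.approx(du_rate, rel=5e-2)
        assert got_di == pytest.approx(di_rate, rel=5e-2)


class TestMovementProbabilities:
    def test_pressure_never_up_gradient(self, params):
        rho = np.array([0.0, 100.0, 400.0, 900.0, 400.0, 100.0, 0.0])
        pk = params.replace(movement="pressure")
        left, right = movement_probabilities(rho, 0.01, pk)
        # climbing towards the peak at index 3 is forbidden
        assert (right[:3] == 0).all()
        assert (left[4:] == 0).all()
        assert right[3] > 0 and left[3] > 0  # peak drains both ways

    def test_pressure_flat_profile_frozen(self, params):
        rho = np.full(9, 500.0)
        pk = params.replace(movement="pressure")
        probs = movement_probabilities(rho, 0.01, pk)
        for F in probs:
            assert (F == 0).all()

    def test_undirected_symmetric_with_walls(self, params):
        rho = np.zeros(5)
        left, right = movement_probabilities(rho, 0.4, params)
        assert left[0] == 0 and right[-1] == 0
        assert (left[1:] == 0.2).all() and (right[:-1] == 0.2).all()

    def test_2d_four_directions(self, params_2d):
        rho = np.zeros((4, 4))
        probs = movement_probabilities(rho, 0.4, params_2d)
        assert len(probs) == 4
        for F in probs:
            assert F.max() == pytest.approx(0.1)


class TestSimulate:
    def test_zero_horizon(self, params, ic):
        traj = simulate(params, ic, horizon=0.0, seed=1)
        assert len(traj.states) == 1
        assert traj.times[0] == 0.0

    def test_determinism(self, params, ic):
        a = simulate(params, ic, horizon=5.0, seed=3, record_every=50)
        b = simulate(params, ic, horizon=5.0, seed=3, record_every=50)
        np.testing.assert_array_equal(a.totals["total_U"], b.totals["total_U"])
        np.testing.assert_array_equal(a.totals["total_I"], b.totals["total_I"])
        np.testing.assert_array_equal(a.states[-1].v, b.states[-1].v)

    def test_seed_sensitivity(self, params, ic):
        a = simulate(params, ic, horizon=5.0, seed=1)
        b = simulate(params, ic, horizon=5.0, seed=2)
        assert (a.states[-1].U != b.states[-1].U).any()

    def test_boundary_warning(self, params):
        ic = no_infection_ic(params, u_radius=1.0)
        with pytest.warns(UserWarning, match="boundary"):
            traj = simulate(params.replace(D_U=0.05, tau=0.005), ic,
                            horizon=30.0, seed=1, half_width=1.4)
        assert traj.meta["boundary_hit"]

    def test_quasi_steady_viral_ratio(self, params, ic):
        # site-wise v*q_v/(alpha*q) tracks i after an initial transient
        traj = simulate(params, ic, horizon=60.0, seed=1, record_every=500,
                        half_width=6.0)
        st = traj.states[-1]
        ratio = st.v * params.q_v / (params.alpha * params.q)
        kernel = np.ones(7) / 7
        sm_ratio = np.convolve(ratio, kernel, mode="same")
        sm_i = np.convolve(st.i, kernel, mode="same")
        assert np.max(np.abs(sm_ratio - sm_i)) < 0.1 * params.K


class TestEnsemble:
    def test_single_replicate_matches_simulate(self, params, ic):
        ens = ensemble(params, ic, horizon=3.0, M=1, base_seed=9,
                       record_every=50)
        traj = simulate(params, ic, horizon=3.0, seed=9, record_every=50)
        np.testing.assert_array_equal(ens.total_U[0], traj.totals["total_U"])

    def test_m_must_be_positive(self, params, ic):
        with pytest.raises(ValueError):
            ensemble(params, ic, horizon=1.0, M=0)

    def test_subcritical_infection_never_kills_tumour(self, params):
        # alpha = 100 gives beta_tilde < q: infection-free state is stable
        pk = params.replace(alpha=100.0)
        ens = ensemble(pk, horizon=30.0, M=3, base_seed=1, record_every=100,
                       half_width=6.0)
        assert not np.isfinite(ens.ext_time_u).any()
        assert (ens.final_U > 0).all()


class Test2D:
    def test_conservation_2d(self, params_2d, rng):
        pk = params_2d.replace(p=0.0, q=0.0, beta=0.0)
        state = uniform_state(U=30, I=5, n=11, dimension=2)
        tot = state.U.sum() + state.I.sum()
        for _ in range(10):
            state = step(state, pk, rng)
        assert state.U.sum() + state.I.sum() == tot

    def test_2d_smoke_and_determinism(self, params_2d):
        pk = params_2d.replace(R_u=1.0, R_v=0.3)
        ic = InitialCondition.from_params(pk)
        a = simulate(pk, ic, horizon=1.0, seed=1, half_width=2.0)
        b = simulate(pk, ic, horizon=1.0, seed=1, half_width=2.0)
        np.testing.assert_array_equal(a.states[-1].U, b.states[-1].U)
        assert a.states[-1].U.shape == (41, 41)
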