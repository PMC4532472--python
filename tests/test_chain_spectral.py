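"""Generator matrices, relaxation time, equilibrium and reduced rate."""

import numpy as np
import pytest
import scipy.linalg

from hypothesis import given, settings
from hypothesis import strategies as st

from chainabridge import (
    ChainSpec,
    build_generator_A,
    build_generator_B,
    detailed_balance_equilibrium,
    equilibrium_distribution,
    reduced_rate,
    relaxation_time,
    spectral_report,
    validity_check,
)
from chainabridge.models import SwitchParams, switch_chain


class TestGenerators:
    def test_two_state_matrix_matches_closed_form(self):
        c1, c2, c3 = 1.3, 0.7, 0.2
        chain = ChainSpec(n=2, forward=(c1,), backward=(c2,), exit_rate=c3)
        np.testing.assert_allclose(
            build_generator_A(chain), [[-c1, c2], [c1, -(c2 + c3)]]
        )
        np.testing.assert_allclose(
            build_generator_B(chain), [[-c1, c2], [c1, -c2]]
        )

    def test_three_state_unit_rates(self):
        chain = ChainSpec(n=3, forward=(1, 1), backward=(1, 1), exit_rate=1)
        np.testing.assert_allclose(
            build_generator_A(chain),
            [[-1, 1, 0], [1, -2, 1], [0, 1, -2]],
        )

    def test_column_sums_express_probability_flux(self, random_chains):
        # B conserves probability everywhere; A leaks -f_n through the exit column
        for chain in random_chains:
            a = build_generator_A(chain)
            b = build_generator_B(chain)
            np.testing.assert_allclose(b.sum(axis=0), 0.0, atol=1e-12)
            expected = np.zeros(chain.n)
            expected[chain.exit_index - 1] = -chain.exit_rate
            np.testing.assert_allclose(a.sum(axis=0), expected, atol=1e-9)

    def test_exit_term_is_rank_one_perturbation(self, random_chains):
        for chain in random_chains[:10]:
            e = build_generator_A(chain) - build_generator_B(chain)
            nz = np.nonzero(e)
            u = chain.exit_index - 1
            assert nz[0].tolist() == [u] and nz[1].tolist() == [u]
            assert e[u, u] == pytest.approx(-chain.exit_rate, rel=1e-12)

    def test_exit_index_places_the_leak(self):
        chain = ChainSpec(
            n=3, forward=(1, 2), backward=(3, 4), exit_rate=0.5, exit_index=2
        )
        e = build_generator_A(chain) - build_generator_B(chain)
        assert e[1, 1] == -0.5 and np.count_nonzero(e) == 1


class TestRelaxationTime:
    def test_two_state_closed_form(self):
        chain = ChainSpec(n=2, forward=(2.5,), backward=(0.5,), exit_rate=1.0)
        assert relaxation_time(chain) == pytest.approx(1.0 / 3.0)

    def test_rate_scaling_inverse_linear(self, random_chains):
        for chain in random_chains[:8]:
            alpha = 7.0
            scaled = ChainSpec(
                n=chain.n,
                forward=tuple(alpha * f for f in chain.forward),
                backward=tuple(alpha * b for b in chain.backward),
                exit_rate=chain.exit_rate,
            )
            assert relaxation_time(scaled) == pytest.approx(
                relaxation_time(chain) / alpha, rel=1e-9
            )

    def test_matches_symmetric_tridiagonal_eigensolver(self):
        # independent oracle: B is similar to a symmetric tridiagonal matrix
        # via the detailed-balance diagonal scaling, solvable with eigh
        p = SwitchParams(k=5.0)
        for clb2 in (1, 5, 10, 20, 35):
            chain = switch_chain(p, float(clb2))
            f = np.array(chain.forward)
            b = np.array(chain.backward)
            diag = np.concatenate([[-f[0]], -(b[:-1] + f[1:]), [-b[-1]]])
            off = np.sqrt(f * b)
            vals = scipy.linalg.eigh_tridiagonal(diag, off)[0]
            expected = 1.0 / abs(np.sort(vals)[-2])
            assert relaxation_time(chain) == pytest.approx(expected, rel=1e-10)

    def test_disconnected_chain_refused(self):
        chain = ChainSpec(n=3, forward=(0.0, 1.0), backward=(0.0, 1.0), exit_rate=0.1)
        with pytest.raises(ValueError, match="disconnected"):
            relaxation_time(chain)

    def test_single_state_has_no_internal_dynamics(self):
        assert relaxation_time(ChainSpec(n=1, forward=(), backward=(), exit_rate=2.0)) == 0.0


class TestEquilibrium:
    def test_uniform_rates_give_uniform_occupancy(self):
        chain = ChainSpec(n=6, forward=(3.0,) * 5, backward=(3.0,) * 5, exit_rate=0.1)
        np.testing.assert_allclose(equilibrium_distribution(chain), np.full(6, 1 / 6))

    def test_detailed_balance_ratios(self, random_chains):
        for chain in random_chains:
            pi = equilibrium_distribution(chain)
            for i in range(chain.n - 1):
                # tiny occupancies carry eps-level absolute error from the
                # solve, so the ratio check is looser than machine precision
                assert pi[i + 1] / pi[i] == pytest.approx(
                    chain.forward[i] / chain.backward[i], rel=1e-5
                )

    def test_is_null_vector_of_B(self, random_chains):
        for chain in random_chains:
            pi = equilibrium_distribution(chain)
            residual = build_generator_B(chain) @ pi
            scale = max(np.abs(build_generator_B(chain)).max(), 1.0)
            assert np.abs(residual).max() < 1e-10 * scale

    def test_linear_solve_agrees_with_closed_form(self, random_chains):
        for chain in random_chains:
            a = equilibrium_distribution(chain)
            b = detailed_balance_equilibrium(chain)
            assert np.abs(a - b).max() < 1e-10
            np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-14)

    def test_truncated_geometric_for_uniform_ratio(self):
        # switch-style chain: forward k*Clb2, backward k*k_p => ratio Clb2/k_p
        p = SwitchParams(k=0.5)
        chain = switch_chain(p, 4.0)
        ratio = 4.0 / p.k_p
        expect = ratio ** np.arange(10)
        expect /= expect.sum()
        np.testing.assert_allclose(equilibrium_distribution(chain), expect, rtol=1e-10)

    def test_reducible_chain_refused(self):
        chain = ChainSpec(n=3, forward=(1.0, 0.0), backward=(1.0, 1.0), exit_rate=0.1)
        with pytest.raises(ValueError, match="irreducible"):
            equilibrium_distribution(chain)


class TestReducedRate:
    def test_two_state_closed_form(self):
        c1, c2, c3 = 2.0, 5.0, 0.3
        chain = ChainSpec(n=2, forward=(c1,), backward=(c2,), exit_rate=c3)
        rr = reduced_rate(chain)
        assert abs(rr.gamma) == pytest.approx(c1 * c3 / (c1 + c2), rel=1e-12)
        assert rr.c_m == pytest.approx(rr.c_single)

    def test_gamma_converges_to_dominant_eigenvalue(self):
        # fixed fast chain, exit rate swept downward: relative gap ~ O(rho)
        base = ChainSpec(n=4, forward=(3.0, 1.0, 2.0), backward=(2.0, 2.0, 1.0),
                         exit_rate=1.0)
        gaps = []
        for fn in (1e-1, 1e-2, 1e-3, 1e-4):
            chain = ChainSpec(n=4, forward=base.forward, backward=base.backward,
                              exit_rate=fn)
            gaps.append(reduced_rate(chain).relative_gap)
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-3

    def test_gap_bounded_by_validity_ratio(self, separated_chains):
        # |lambda_n - gamma| / |lambda_n| = O(rho); constant 10 covers the suite
        for chain in separated_chains:
            rho, _ = validity_check(chain)
            assert reduced_rate(chain).relative_gap <= 10.0 * rho

    def test_m_particles_multiply_the_rate(self):
        chain = ChainSpec(n=3, forward=(5.0, 5.0), backward=(5.0, 5.0),
                          exit_rate=0.01, particles=7)
        rr = reduced_rate(chain)
        assert rr.c_m == pytest.approx(7 * rr.c_single)


class TestValidity:
    def test_zero_exit_rate_always_valid(self):
        chain = ChainSpec(n=3, forward=(1, 1), backward=(1, 1), exit_rate=0.0)
        assert validity_check(chain) == (0.0, True)

    def test_two_state_ratio_formula(self):
        # rho = c3/(c1+c2): small when either c1 or c2 dominates c3
        for c1, c2, c3, expect_valid in [
            (1.0, 100.0, 1.0, True),
            (100.0, 1.0, 1.0, True),
            (1.0, 1.0, 1.0, False),
        ]:
            chain = ChainSpec(n=2, forward=(c1,), backward=(c2,), exit_rate=c3)
            rho, valid = validity_check(chain)
            assert rho == pytest.approx(c3 / (c1 + c2))
            assert valid is expect_valid

    def test_rho_scales_inversely_with_chain_speed(self):
        # switch chain at Clb2=10: rho differs by 500x between k=5 and k=0.01
        def rho_at(k):
            p = SwitchParams(k=k)
            chain = switch_chain(p, 10.0)
            chain = ChainSpec(n=chain.n, forward=chain.forward,
                              backward=chain.backward, exit_rate=1.0)
            return validity_check(chain)[0]

        assert rho_at(0.01) / rho_at(5.0) == pytest.approx(500.0, rel=1e-9)


class TestSpectralReport:
    def test_random_chain_invariants(self, random_chains):
        for chain in random_chains[:25]:
            rep = spectral_report(chain)
            assert np.all(rep.eigenvalues_A < 0)
            scale = np.abs(rep.eigenvalues_B).max()
            assert np.all(rep.eigenvalues_B[:-1] < 0)
            assert abs(rep.eigenvalues_B[-1]) < 1e-9 * max(scale, 1.0)
            assert rep.equilibrium.min() >= 0
            assert rep.equilibrium.sum() == pytest.approx(1.0)
            diff = rep.eigenvalues_B - rep.eigenvalues_A
            assert np.all(diff >= -1e-8 * max(scale, 1.0))
            assert np.all(diff <= chain.exit_rate + 1e-8 * max(scale, 1.0))
            assert rep.c_single <= chain.exit_rate * (1 + 1e-9)

    def test_characteristic_polynomial_two_state(self):
        # f1 = b1 = f2 = 1: eigenvalues of A are the roots of x^2 + 3x + 1
        chain = ChainSpec(n=2, forward=(1.0,), backward=(1.0,), exit_rate=1.0)
        rep = spectral_report(chain)
        np.testing.assert_allclose(rep.eigenvalues_A, np.sort(np.roots([1, 3, 1])))

    def test_degenerate_single_state(self):
        rep = spectral_report(ChainSpec(n=1, forward=(), backward=(), exit_rate=0.7))
        assert rep.gamma == -0.7
        assert rep.T_relax == 0.0
        assert rep.c_single == pytest.approx(0.7)


_rate = st.floats(min_value=1e-3, max_value=1e3)


@given(
    data=st.integers(min_value=2, max_value=8).flatmap(
        lambda n: st.tuples(
            st.lists(_rate, min_size=n - 1, max_size=n - 1),
            st.lists(_rate, min_size=n - 1, max_size=n - 1),
            _rate,
        )
    )
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_rank_one_interlacing_holds_for_arbitrary_chains(data):
    """Removing the exit shifts every eigenvalue upward by at most f_n."""
    forward, backward, exit_rate = data
    chain = ChainSpec(
        n=len(forward) + 1, forward=tuple(forward), backward=tuple(backward),
        exit_rate=exit_rate,
    )
    rep = spectral_report(chain)  # raises internally if the bound fails
    diff = rep.eigenvalues_B - rep.eigenvalues_A
    scale = max(np.abs(rep.eigenvalues_B).max(), exit_rate, 1.0)
    assert np.all(diff >= -1e-8 * scale)
    assert np.all(diff <= exit_rate + 1e-8 * scale)
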