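"""Matrix doubling: combination algebra, energy bookkeeping, convergence."""

import math
import warnings

import numpy as np
import pytest

from mtvm.matrix_doubling import (AngularGrid, LayerOperators,
                                  backscatter_sigma0, combine_layers,
                                  power_balance, stack_canopy, stack_uniform,
                                  thin_layer_operators)
from mtvm.scatterer_models import PhaseField, layer_phase_matrix


def scalar_layer(s, t, na=1, n=1):
    S = np.zeros((na, n, n))
    T = np.zeros((na, n, n))
    S[0, 0, 0] = s
    T[0, 0, 0] = t
    return LayerOperators(S, T, S.copy(), T.copy(), 1.0)


def random_layer(rng, na=4, n=6, scale=0.05):
    s = scale * rng.random((na, n, n))
    t = scale * rng.random((na, n, n))
    t[0] += np.diag(0.7 + 0.2 * rng.random(n))
    ss = scale * rng.random((na, n, n))
    ts = scale * rng.random((na, n, n))
    ts[0] += np.diag(0.7 + 0.2 * rng.random(n))
    return LayerOperators(s, t, ss, ts, 1.0)


class TestAngularGrid:
    def test_weights_normalized_and_positive(self, grid):
        assert grid.w.sum() == pytest.approx(1.0, abs=1e-13)
        assert np.all(grid.w > 0)
        assert np.all((grid.mu > 0) & (grid.mu < 1))

    def test_incidence_node_present(self, grid):
        k0 = grid.node_index(43.0)
        assert grid.mu[k0] == pytest.approx(math.cos(math.radians(43.0)),
                                            abs=1e-15)

    def test_missing_node_raises(self, grid):
        with pytest.raises(ValueError, match="not a grid node"):
            grid.node_index(37.0)

    def test_odd_azimuth_rejected(self):
        with pytest.raises(ValueError):
            AngularGrid.build(n_zenith=4, n_azimuth=7)


class TestThinLayer:
    def test_empty_layer_is_vacuum(self, grid):
        n = grid.n_states
        pf = PhaseField(p=np.zeros((2, 2, 2, 2, 8, 8, 16)),
                        kappa=np.zeros((2, 2, 8)))
        ops = thin_layer_operators(pf, 1.0, grid)
        assert np.abs(ops.S).max() == 0.0
        assert np.abs(ops.T[0] - np.eye(n)).max() == 0.0
        assert np.abs(ops.T[1:]).max() == 0.0

    def test_scattered_parts_linear_in_dz(self, kernels_a, grid):
        pf = layer_phase_matrix([1e-6, 1e-6], kernels_a)
        o1 = thin_layer_operators(pf, 0.5, grid)
        o2 = thin_layer_operators(pf, 1.0, grid)
        assert np.allclose(o2.S, 2.0 * o1.S, rtol=1e-12)
        assert np.allclose(o2.S_star, 2.0 * o1.S_star, rtol=1e-12)

    def test_pure_absorber_matches_beer_lambert(self, grid):
        kappa = 0.03
        pf = PhaseField(p=np.zeros((2, 2, 2, 2, 8, 8, 16)),
                        kappa=np.full((2, 2, 8), kappa))
        ops = thin_layer_operators(pf, 2.0, grid)
        want = np.exp(-kappa * 2.0 / grid.mu)
        got = np.diag(ops.T[0])[0::2]
        assert np.abs(got - want).max() < 1e-12
        assert np.abs(np.diag(ops.T_star[0])[1::2] - want).max() < 1e-12

    def test_nonfinite_phase_rejected(self, grid):
        p = np.zeros((2, 2, 2, 2, 8, 8, 16))
        p[0, 0, 0, 0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            thin_layer_operators(PhaseField(p=p, kappa=np.zeros((2, 2, 8))),
                                 1.0, grid)

    def test_thick_layer_warns(self, grid):
        pf = PhaseField(p=np.zeros((2, 2, 2, 2, 8, 8, 16)),
                        kappa=np.full((2, 2, 8), 0.5))
        with pytest.warns(UserWarning, match="precondition"):
            thin_layer_operators(pf, 1.0, grid)


class TestCombination:
    def test_vacuum_neutral_element(self, rng):
        lay = random_layer(rng)
        vac = LayerOperators.vacuum(6, 4)
        for combo in (combine_layers(lay, vac), combine_layers(vac, lay)):
            assert np.abs(combo.S - lay.S).max() < 1e-14
            assert np.abs(combo.T - lay.T).max() < 1e-14

    def test_scalar_two_layer_matches_bounce_series(self):
        lay = scalar_layer(0.1, 0.8)
        combo = combine_layers(lay, lay)
        # independent geometric bounce-series oracle
        s_orc = 0.1 + sum(0.8 * 0.1 * (0.1 * 0.1) ** m * 0.8
                          for m in range(200))
        t_orc = sum(0.8 * (0.1 * 0.1) ** m * 0.8 for m in range(200))
        assert combo.S[0, 0, 0] == pytest.approx(s_orc, abs=1e-12)
        assert combo.T[0, 0, 0] == pytest.approx(t_orc, abs=1e-12)
        assert combo.S[0, 0, 0] == pytest.approx(0.1 + 0.064 / 0.99,
                                                 abs=1e-12)
        assert combo.T[0, 0, 0] == pytest.approx(0.64 / 0.99, abs=1e-12)

    def test_associativity(self, rng):
        l1, l2, l3 = (random_layer(rng) for _ in range(3))
        a = combine_layers(combine_layers(l1, l2), l3)
        b = combine_layers(l1, combine_layers(l2, l3))
        for x, y in ((a.S, b.S), (a.T, b.T), (a.S_star, b.S_star),
                     (a.T_star, b.T_star)):
            assert np.abs(x - y).max() <= 1e-10 * max(np.abs(y).max(), 1.0)

    def test_neumann_series_equivalence(self, rng):
        """On a small toy grid the combination equals the explicit sum over
        bounce orders between the two slabs."""
        na, n = 2, 3
        l1 = random_layer(rng, na=na, n=n, scale=0.04)
        l2 = random_layer(rng, na=na, n=n, scale=0.04)
        combo = combine_layers(l1, l2)

        def conv(a, b):
            # circular convolution over the azimuth-difference index
            out = np.zeros_like(a)
            for la in range(na):
                for lb in range(na):
                    out[(la + lb) % na] += a[la] @ b[lb]
            return out

        # explicit series: S = S1 + T1* S2 sum_k (S1* S2)^k T1
        bounce = conv(l1.S_star, l2.S)
        acc = np.zeros_like(l1.S)
        power = np.zeros_like(l1.S)
        power[0] = np.eye(n)
        for _ in range(80):
            acc += power
            power = conv(bounce, power)
        s_total = l1.S + conv(conv(l1.T_star, l2.S), conv(acc, l1.T))
        assert np.abs(s_total - combo.S).max() < 1e-12

    def test_incompatible_grids_rejected(self, rng):
        with pytest.raises(ValueError):
            combine_layers(random_layer(rng, n=6), random_layer(rng, n=4))


class TestStacking:
    def test_four_layers_sequential_vs_doubling(self, rng):
        lay = random_layer(rng)
        seq = stack_canopy([lay] * 4)
        dbl = stack_uniform(lay, 4)
        assert np.abs(seq.S - dbl.S).max() < 1e-12
        assert np.abs(seq.T_star - dbl.T_star).max() < 1e-12

    def test_single_layer_identity(self, rng):
        lay = random_layer(rng)
        out = stack_canopy([lay])
        assert np.abs(out.S - lay.S).max() < 1e-14

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            stack_canopy([])

    def test_optically_thin_canopy_matches_first_order(self, kernels_a, grid):
        """tau < 0.01: sigma0 agrees with the single-scattering closed form
        (attenuated first-order radiative transfer solution) within 1%."""
        dens = 2e-8
        pf = layer_phase_matrix([dens, dens], kernels_a)
        ops = thin_layer_operators(pf, 1.0, grid)
        n_lay = 40
        total = stack_canopy([ops] * n_lay)
        sig = backscatter_sigma0(total, 43.0, "VV", grid)
        k0 = grid.node_index(43.0)
        mu0 = grid.mu[k0]
        l_back = grid.n_azimuth // 2
        p_back = pf.p[0, 0, 0, 1, k0, k0, l_back]
        kappa = pf.kappa[0, 1, k0]
        z0 = float(n_lay)
        lin = 4.0 * math.pi * p_back * mu0 \
            * (1.0 - math.exp(-2.0 * kappa * z0 / mu0)) / (2.0 * kappa)
        assert sig.linear == pytest.approx(lin, rel=0.01)
        assert pf.kappa.max() * z0 / mu0 < 0.01  # the regime really is thin


class TestSigmaZero:
    def test_zero_canopy_sentinel(self, grid):
        vac = LayerOperators.vacuum(grid.n_states, grid.n_azimuth)
        sig = backscatter_sigma0(vac, 43.0, "VV", grid)
        assert sig.value_db == -math.inf
        assert sig.linear == 0.0

    def test_off_grid_incidence_rejected(self, grid):
        vac = LayerOperators.vacuum(grid.n_states, grid.n_azimuth)
        with pytest.raises(ValueError, match="not a grid node"):
            backscatter_sigma0(vac, 37.0, "VV", grid)

    def test_unknown_channel_rejected(self, grid):
        vac = LayerOperators.vacuum(grid.n_states, grid.n_azimuth)
        with pytest.raises(ValueError):
            backscatter_sigma0(vac, 43.0, "VX", grid)


class TestEnergyAndConvergence:
    def test_passive_layer_energy_balance(self, kernels_a, kernels_b, grid):
        for kerns in (kernels_a, kernels_b):
            pf = layer_phase_matrix([8e-5, 8e-5], kerns)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ops = thin_layer_operators(pf, 1.0, grid)
            assert power_balance(ops, grid).max() <= 1.0 + 1e-9

    def test_lossless_layer_energy_closure(self, grid):
        """Without absorption the outgoing power equals the incoming power
        up to the O(tau^2) discretization of a thin slab."""
        from mtvm.dielectric import ComplexPermittivity
        from mtvm.scatterer_models import ScattererSpec, species_kernels

        lossless = ScattererSpec("disc", 1.0, 0.02,
                                 ComplexPermittivity(4.0, 0.0),
                                 "physical_optics")
        kern = species_kernels(lossless, 5.3, grid)
        dens = 1e-6
        pf = layer_phase_matrix([dens], [kern])
        ops = thin_layer_operators(pf, 1.0, grid)
        pb = power_balance(ops, grid)
        assert pb.max() <= 1.0 + 1e-9
        assert pb.min() >= 1.0 - 1e-6

    def test_dz_convergence(self, kernels_a, grid):
        """Halving dz changes sigma0 by well under 0.05 dB."""
        sig = {}
        for dz in (1.0, 0.5):
            layers = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pf = layer_phase_matrix([8e-5 / 3.0, 8e-5 / 3.0], kernels_a)
                ops = thin_layer_operators(pf, dz, grid)
            layers = [ops] * int(round(60.0 / dz))
            tot = stack_canopy(layers)
            sig[dz] = backscatter_sigma0(tot, 43.0, "VV", grid).value_db
        assert abs(sig[1.0] - sig[0.5]) < 0.05

    def test_angular_convergence(self, kernels_a, grid):
        """Doubling both angular resolutions changes sigma0 by < 0.1 dB."""
        from mtvm.presets import canopy_species
        from mtvm.scatterer_models import species_kernels

        fine = AngularGrid.build(n_zenith=16, n_azimuth=32, theta_inc_deg=43.0)
        kerns_fine = [species_kernels(s, 5.3, fine)
                      for s in canopy_species("A", 5.3)]
        sig = {}
        for g, kerns in ((grid, kernels_a), (fine, kerns_fine)):
            pf = layer_phase_matrix([8e-5 / 3.0, 8e-5 / 3.0], kerns)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ops = thin_layer_operators(pf, 1.0, g)
            tot = stack_canopy([ops] * 60)
            sig[g.mu.size] = backscatter_sigma0(tot, 43.0, "VV", g).value_db
        assert abs(sig[8] - sig[16]) < 0.1
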