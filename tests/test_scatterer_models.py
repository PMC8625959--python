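"""Single-scatterer amplitudes: limits, reciprocity, independent oracles."""

import math

import numpy as np
import pytest

from mtvm.dielectric import ComplexPermittivity, vegetation_permittivity
from mtvm.scatterer_models import (DirectionPair, ScattererSpec,
                                   cylinder_scattering_infinite,
                                   disc_scattering_po,
                                   extinction_cross_section,
                                   layer_phase_matrix, needle_scattering_rg,
                                   wavenumber, direction,
                                   pol_basis)
from mtvm import scatterer_models as sm

EPS_A = vegetation_permittivity(0.85, 5.3)
EPS_B = vegetation_permittivity(0.6, 5.3)
VACUUM = ComplexPermittivity(1.0, 0.0)
ETA = np.array([[1.0, -1.0], [-1.0, 1.0]])

DISC = ScattererSpec("disc", 3.0, 0.02, EPS_A, "physical_optics")
NEEDLE = ScattererSpec("cylinder", 0.3, 4.0, EPS_B, "rayleigh_gans",
                       axis=(1.0, 0.0, 0.0))
STALK = ScattererSpec("cylinder", 1.25, 10.0, EPS_A, "infinite_cylinder")


def rg_disc_oracle(radius, thickness, eps, freq, dirs):
    """Independent Rayleigh-Gans thin-disc closed form (horizontal disc).

    Tangential polarizability (eps - 1), normal (eps - 1)/eps, disc form
    factor jinc in the transverse and sinc in the normal momentum transfer.
    Written from scratch against the implementation.
    """
    from scipy.special import j1

    k = wavenumber(freq)
    n = np.array([0.0, 0.0, 1.0])
    ki, ks = dirs.ki, dirs.ks
    q = k * (ki - ks)
    qn = q @ n
    qt = np.linalg.norm(q - qn * n)
    f_ax = np.sinc(qn * thickness / 2.0 / np.pi)
    f_t = 1.0 if qt * radius < 1e-12 else 2.0 * j1(qt * radius) / (qt * radius)
    vol = np.pi * radius ** 2 * thickness
    vi, hi = pol_basis(ki)
    vs, hs = pol_basis(ks)
    out = np.empty((2, 2), dtype=complex)
    for p, ps in enumerate((vs, hs)):
        for qx, qi in enumerate((vi, hi)):
            contr = (eps - 1.0) * (ps @ qi - (ps @ n) * (qi @ n)) \
                + (eps - 1.0) / eps * (ps @ n) * (qi @ n)
            out[p, qx] = k * k * vol / (4.0 * np.pi) * f_ax * f_t * contr
    return out


def born_volume_oracle(spec, freq, dirs, n_cells=40):
    """Brute-force volume-integral discretization of the Born-type amplitude.

    Voxelizes the cylinder, applies the same quasistatic internal-field
    tensor, and sums exp(i q . r) cell by cell; independent of the
    closed-form form factors in the implementation.
    """
    k = wavenumber(freq)
    eps = spec.permittivity.physics
    a = np.asarray(spec.axis, dtype=float)
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else \
        np.array([1.0, 0.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    r, length = spec.radius, spec.thickness_or_length
    ax = np.linspace(-length / 2, length / 2, n_cells, endpoint=False) \
        + length / n_cells / 2
    xs = np.linspace(-r, r, n_cells, endpoint=False) + r / n_cells
    xg, yg = np.meshgrid(xs, xs, indexing="ij")
    inside = xg ** 2 + yg ** 2 <= r ** 2
    pts = (xg[inside][:, None] * e1 + yg[inside][:, None] * e2)
    cell_vol = (2 * r / n_cells) ** 2 * (length / n_cells)
    q = k * (dirs.ki - dirs.ks)
    vi, hi = pol_basis(dirs.ki)
    vs, hs = pol_basis(dirs.ks)
    phase_t = np.exp(1j * pts @ q)
    phase_a = np.exp(1j * ax * (a @ q))
    total_phase = phase_t.sum() * phase_a.sum() * cell_vol
    t_perp = (eps - 1.0) * 2.0 / (eps + 1.0)
    t_par = eps - 1.0
    out = np.empty((2, 2), dtype=complex)
    for p, ps in enumerate((vs, hs)):
        for qx, qi in enumerate((vi, hi)):
            contr = t_perp * (ps @ qi - (ps @ a) * (qi @ a)) \
                + t_par * (ps @ a) * (qi @ a)
            out[p, qx] = k * k / (4.0 * np.pi) * contr * total_phase
    return out


def random_pair(rng):
    ti, ts = rng.uniform(0.2, math.pi - 0.2, size=2)
    fi, fs = rng.uniform(0.0, 2 * math.pi, size=2)
    return DirectionPair(ti, fi, ts, fs)


class TestLimits:
    @pytest.mark.parametrize("maker", [
        lambda d: disc_scattering_po(
            ScattererSpec("disc", 3.0, 0.02, VACUUM, "physical_optics"),
            5.3, d),
        lambda d: needle_scattering_rg(
            ScattererSpec("cylinder", 0.3, 4.0, VACUUM, "rayleigh_gans"),
            5.3, d),
        lambda d: cylinder_scattering_infinite(
            ScattererSpec("cylinder", 1.0, 10.0, VACUUM, "infinite_cylinder"),
            5.3, d),
    ])
    def test_vacuum_scatterer_is_silent(self, maker):
        d = DirectionPair(2.0, 0.0, 1.0, 2.0)
        assert np.abs(maker(d)).max() < 1e-12

    def test_nonphysical_permittivity_rejected(self):
        with pytest.raises(ValueError):
            ComplexPermittivity(0.9, 1.0)

    def test_thick_disc_warns(self):
        fat = ScattererSpec("disc", 3.0, 1.5, EPS_A, "physical_optics")
        with pytest.warns(UserWarning, match="electrically thin"):
            disc_scattering_po(fat, 9.6, DirectionPair(2.0, 0.0, 1.0, 1.0))

    def test_fat_needle_warns(self):
        fat = ScattererSpec("cylinder", 1.25, 10.0, EPS_A, "rayleigh_gans")
        with pytest.warns(UserWarning, match="slender"):
            needle_scattering_rg(fat, 9.6, DirectionPair(2.0, 0.0, 1.0, 1.0))


class TestCrossModelConsistency:
    def test_small_disc_matches_rg_oracle(self, rng):
        small = ScattererSpec("disc", 0.4, 0.02, EPS_A, "physical_optics")
        for _ in range(8):
            d = random_pair(rng)
            got = disc_scattering_po(small, 1.2, d)
            want = rg_disc_oracle(0.4, 0.02, EPS_A.physics, 1.2, d)
            # bistatic cross sections within 5 %
            assert np.abs(got) ** 2 == pytest.approx(np.abs(want) ** 2,
                                                     rel=0.05, abs=1e-18)

    def test_needle_matches_born_volume_integral(self, rng):
        small = ScattererSpec("cylinder", 0.05, 2.0, EPS_B, "rayleigh_gans",
                              axis=(0.0, 0.0, 1.0))
        for _ in range(4):
            d = random_pair(rng)
            got = needle_scattering_rg(small, 1.2, d)
            want = born_volume_oracle(small, 1.2, d)
            assert np.abs(got - want).max() <= 0.02 * np.abs(want).max()

    def test_thin_cylinder_agrees_with_rg(self, rng):
        # shared validity region: radius well below the RG threshold
        thin = ScattererSpec("cylinder", 0.1, 30.0, EPS_B,
                             "infinite_cylinder")
        thin_rg = ScattererSpec("cylinder", 0.1, 30.0, EPS_B, "rayleigh_gans")
        for _ in range(6):
            d = random_pair(rng)
            a1 = cylinder_scattering_infinite(thin, 1.2, d)
            a2 = needle_scattering_rg(thin_rg, 1.2, d)
            assert np.abs(a1 - a2).max() <= 0.05 * np.abs(a2).max()

    def test_axial_pattern_peaks_on_specular_cone(self):
        # vertical cylinder: the sinc axial factor is maximal where the
        # scattered axial wavenumber matches the incident one; a long
        # cylinder makes the axial lobe narrow enough that the slowly
        # varying transverse factor cannot displace the peak
        theta_i = math.radians(137.0)   # down-going at 43 deg off nadir
        spec = ScattererSpec("cylinder", 0.2, 100.0, EPS_B,
                             "infinite_cylinder")
        thetas = np.linspace(math.radians(130.0), math.radians(144.0), 281)
        amps = []
        for ts in thetas:
            d = DirectionPair(theta_i, 0.0, float(ts), 1.0)
            amps.append(np.abs(
                cylinder_scattering_infinite(spec, 5.3, d))[0, 0])
        peak = thetas[int(np.argmax(amps))]
        assert abs(peak - theta_i) < math.radians(0.5)


class TestReciprocity:
    @pytest.mark.parametrize("spec, op", [
        (DISC, disc_scattering_po),
        (NEEDLE, needle_scattering_rg),
        (STALK, cylinder_scattering_infinite),
    ], ids=["disc", "needle", "cylinder"])
    def test_amplitude_reciprocity(self, spec, op, rng):
        for _ in range(5):
            d = random_pair(rng)
            fwd = op(spec, 5.3, d)
            rev = op(spec, 5.3, d.reversed())
            scale = np.abs(fwd).max()
            assert np.abs(fwd - ETA * rev.T).max() <= 1e-10 * scale

    def test_vertical_needle_azimuthal_symmetry(self):
        spec = ScattererSpec("cylinder", 0.3, 4.0, EPS_B, "rayleigh_gans",
                             axis=(0.0, 0.0, 1.0))
        d0 = DirectionPair(2.0, 0.3, 1.1, 1.4)
        d1 = DirectionPair(2.0, 0.3 + 1.0, 1.1, 1.4 + 1.0)
        a0 = needle_scattering_rg(spec, 5.3, d0)
        a1 = needle_scattering_rg(spec, 5.3, d1)
        assert np.abs(np.abs(a0) - np.abs(a1)).max() < 1e-12


class TestExtinction:
    def test_vacuum_zero(self):
        spec = ScattererSpec("disc", 3.0, 0.02, VACUUM, "physical_optics")
        assert extinction_cross_section(spec, 5.3, 2.0, "v") == 0.0

    def test_lossless_extinction_equals_scattering(self):
        lossless = ComplexPermittivity(5.0, 0.0)
        spec = ScattererSpec("cylinder", 0.3, 4.0, lossless, "rayleigh_gans")
        ext = extinction_cross_section(spec, 5.3, 2.0, "v")
        # independent angular quadrature of the bistatic pattern
        n_t, n_p = 48, 48
        x, w = np.polynomial.legendre.leggauss(n_t)
        phis = 2 * np.pi * (np.arange(n_p) + 0.5) / n_p
        total = 0.0
        for xx, ww in zip(x, w):
            for ph in phis:
                d = DirectionPair(2.0, 0.0, float(np.arccos(xx)), float(ph))
                amp = needle_scattering_rg(spec, 5.3, d)
                total += ww * (2 * np.pi / n_p) * (
                    abs(amp[0, 0]) ** 2 + abs(amp[1, 0]) ** 2)
        assert ext == pytest.approx(total, rel=0.03)

    def test_extinction_grows_with_loss(self):
        e1 = extinction_cross_section(
            ScattererSpec("disc", 3.0, 0.02, ComplexPermittivity(20.0, 2.0),
                          "physical_optics"), 5.3, 2.2, "h")
        e2 = extinction_cross_section(
            ScattererSpec("disc", 3.0, 0.02, ComplexPermittivity(20.0, 8.0),
                          "physical_optics"), 5.3, 2.2, "h")
        assert e2 > e1

    def test_cylinder_absorption_positive(self):
        ext = extinction_cross_section(STALK, 5.3, 2.2, "v")
        sca = sm._scattering_cross_section(STALK, 5.3, direction(2.2, 0.0), 0)
        assert ext > sca > 0


class TestLayerPhaseMatrix:
    def test_single_species_proportionality(self, kernels_a):
        leaf = kernels_a[0]
        pf = layer_phase_matrix([2.5e-5], [leaf])
        assert np.allclose(pf.p, 2.5e-5 * leaf.pk)
        assert np.allclose(pf.kappa, 2.5e-5 * leaf.sig_e)

    def test_linearity_in_counts(self, kernels_a):
        pf1 = layer_phase_matrix([1e-5, 2e-5], kernels_a)
        pf2 = layer_phase_matrix([2e-5, 4e-5], kernels_a)
        assert np.allclose(pf2.p, 2.0 * pf1.p)

    def test_two_species_equals_elementwise_sum(self, kernels_a):
        pf = layer_phase_matrix([1e-5, 3e-5], kernels_a)
        brute = 1e-5 * kernels_a[0].pk + 3e-5 * kernels_a[1].pk
        assert np.abs(pf.p - brute).max() <= 1e-12 * np.abs(brute).max()

    def test_mismatched_species_lists_error(self, kernels_a):
        with pytest.raises(ValueError):
            layer_phase_matrix([1e-5], kernels_a)
        with pytest.raises(ValueError):
            layer_phase_matrix([], [])

    def test_phase_entries_nonnegative(self, kernels_a, kernels_b):
        for kerns in (kernels_a, kernels_b):
            for k in kerns:
                assert np.all(k.pk >= 0.0)
                assert np.all(k.sig_e >= k.sig_a)
                assert np.all(k.sig_a >= 0.0)
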