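"""Single-scatterer electromagnetics for vegetation components.

Three scattering approximations are provided, matching the component types of
the two model canopies:

* broad (disc) leaves — a Kirchhoff / physical-optics thin dielectric disc:
  the induced polarization current is taken from the quasistatic internal
  field of an infinite dielectric slab (tangential E unchanged, normal E
  divided by eps), radiated over the finite disc. This is the thin-disc limit
  of the Le Vine-type physical-optics disc and is exactly reciprocal.
* needle leaves — a generalized Rayleigh-Gans slender cylinder: the internal
  field uses the quasistatic depolarization of an infinite thin rod (axial E
  unchanged, transverse E scaled by 2/(eps+1)), with the axial sinc and
  radial jinc form factors of the finite cylinder.
* stalks / branches — the infinite-length cylinder approximation: the exact
  modal (Bessel-series) internal field of an obliquely illuminated infinite
  dielectric cylinder, radiated over the finite length (sinc-type axial
  pattern). Because the internal field solves the infinite problem only for
  the actual incident direction, the raw amplitude is not exactly
  reciprocal; the returned amplitude is reciprocity-symmetrized.

Conventions. Directions are unit vectors with z up; a propagation direction
d(theta, phi) has polar angle theta from +z. The linear polarization basis at
each direction is h = z x d / |z x d|, v = h x d. Scattering amplitudes F
(cm) are defined by E_s = (e^{ikr}/r) F E_i in the physics time convention
(eps = eps' + i eps''); only |F|^2 couplings and cross sections reach the
radiative transfer layer, so the convention is internal. Under direction
reversal this basis gives the reciprocity relation
F_pq(i -> s) = eta F_qp(-s -> -i) with eta = +1 for co-polarized and -1 for
cross-polarized elements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .dielectric import ComplexPermittivity

__all__ = [
    "ScattererSpec",
    "DirectionPair",
    "SpeciesKernels",
    "PhaseField",
    "scattering_amplitude",
    "disc_scattering_po",
    "needle_scattering_rg",
    "cylinder_scattering_infinite",
    "extinction_cross_section",
    "species_kernels",
    "layer_phase_matrix",
]

#: Speed of light in cm * GHz.
C_CM_GHZ = 29.9792458

_POLS = ("v", "h")


def wavenumber(frequency_ghz: float) -> float:
    """Free-space wavenumber in cm^-1."""
    return 2.0 * math.pi * frequency_ghz / C_CM_GHZ


def direction(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def pol_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(v_hat, h_hat) for propagation direction(s) d, shape (..., 3)."""
    d = np.asarray(d, dtype=float)
    z = np.zeros_like(d)
    z[..., 2] = 1.0
    h = np.cross(z, d)
    nrm = np.linalg.norm(h, axis=-1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise ValueError("polarization basis undefined for vertical propagation")
    h = h / nrm
    v = np.cross(h, d)
    return v, h


@dataclass(frozen=True)
class DirectionPair:
    """Incident and scattered propagation directions (radians)."""

    theta_i: float
    phi_i: float
    theta_s: float
    phi_s: float

    @property
    def ki(self) -> np.ndarray:
        return direction(self.theta_i, self.phi_i)

    @property
    def ks(self) -> np.ndarray:
        return direction(self.theta_s, self.phi_s)

    def reversed(self) -> "DirectionPair":
        """The reciprocal geometry (-s -> -i)."""
        return DirectionPair(
            theta_i=math.pi - self.theta_s, phi_i=self.phi_s + math.pi,
            theta_s=math.pi - self.theta_i, phi_s=self.phi_i + math.pi,
        )


@dataclass(frozen=True)
class ScattererSpec:
    """One vegetation component type.

    ``radius`` and ``thickness_or_length`` are in cm (disc thickness for
    discs, cylinder length for cylinders). ``axis`` is the disc normal or the
    cylinder axis; the canonical orientations of the model canopies are
    horizontal plates (axis = z) and vertical stalks/branches (axis = z).
    ``randomize_azimuth`` marks a horizontal component whose in-plane
    orientation is uniformly random (needle leaves); it affects only the
    orientation-averaged layer kernels, not the single-orientation amplitude.
    """

    shape: str  # 'disc' | 'cylinder'
    radius: float
    thickness_or_length: float
    permittivity: ComplexPermittivity
    approximation: str  # 'physical_optics' | 'rayleigh_gans' | 'infinite_cylinder'
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    randomize_azimuth: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "cylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.radius <= 0 or self.thickness_or_length <= 0:
            raise ValueError("scatterer dimensions must be positive")
        if self.approximation not in (
            "physical_optics", "rayleigh_gans", "infinite_cylinder"
        ):
            raise ValueError(f"unknown approximation {self.approximation!r}")
        n = np.linalg.norm(self.axis)
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            object.__setattr__(
                self, "axis", tuple(np.asarray(self.axis, float) / n)
            )

    @property
    def volume(self) -> float:
        return math.pi * self.radius ** 2 * self.thickness_or_length

    @property
    def eps(self) -> complex:
        """Physics-convention permittivity eps' + i eps''."""
        return self.permittivity.physics


def _jinc(x: np.ndarray) -> np.ndarray:
    """2 J1(x) / x with the x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = 2.0 * special.j1(x[nz]) / x[nz]
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    return np.sinc(np.asarray(x) / np.pi)


# ---------------------------------------------------------------------------
# Born-type amplitudes (disc PO, needle RG)
# ---------------------------------------------------------------------------

def _born_amp_grid(spec: ScattererSpec, k: float, ki: np.ndarray,
                   ks: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Vectorized Born-type 2x2 amplitude for broadcastable ki, ks (...,3).

    Returns array of shape (2, 2) + broadcast shape; index order
    [pol_s, pol_i] with 0 = v, 1 = h.
    """
    eps = spec.eps
    ki, ks = np.broadcast_arrays(np.asarray(ki, float), np.asarray(ks, float))
    vi, hi = pol_basis(ki)
    vs, hs = pol_basis(ks)
    q = k * (ki - ks)
    qa = np.einsum("...i,i->...", q, axis)
    qt = np.linalg.norm(q - qa[..., None] * axis, axis=-1)

    if spec.shape == "disc":
        a, d = spec.radius, spec.thickness_or_length
        ff = _sinc(qa * d / 2.0) * _jinc(qt * a)
        t_par = eps - 1.0            # in-plane (tangential) polarizability
        t_ax = (eps - 1.0) / eps     # along the normal
    else:
        r, length = spec.radius, spec.thickness_or_length
        ff = _sinc(qa * length / 2.0) * _jinc(qt * r)
        t_par = (eps - 1.0) * 2.0 / (eps + 1.0)  # transverse to the axis
        t_ax = eps - 1.0                          # along the axis

    pref = (k * k * spec.volume / (4.0 * math.pi)) * ff

    pol_s = (vs, hs)
    pol_i = (vi, hi)
    out = np.empty((2, 2) + ff.shape, dtype=complex)
    for p, ps in enumerate(pol_s):
        psa = np.einsum("...i,i->...", ps, axis)
        for qx, qi in enumerate(pol_i):
            qia = np.einsum("...i,i->...", qi, axis)
            dot = np.einsum("...i,...i->...", ps, qi)
            contr = t_par * (dot - psa * qia) + t_ax * psa * qia
            out[p, qx] = pref * contr
    return out


def disc_scattering_po(spec: ScattererSpec, frequency_ghz: float,
                       dirs: DirectionPair) -> np.ndarray:
    """Physical-optics amplitude matrix of a thin dielectric disc, cm.

    Rows are scattered polarization (v, h), columns incident polarization.
    """
    if spec.shape != "disc":
        raise ValueError("disc_scattering_po requires a disc spec")
    if spec.permittivity.real < 1.0:
        raise ValueError("nonphysical permittivity: real part < 1")
    k = wavenumber(frequency_ghz)
    if k * spec.thickness_or_length * math.sqrt(abs(spec.eps)) > 0.5:
        warnings.warn(
            "disc is not electrically thin; the physical-optics slab "
            "internal field is inaccurate", stacklevel=2,
        )
    return _born_amp_grid(spec, k, dirs.ki, dirs.ks, np.asarray(spec.axis))


def needle_scattering_rg(spec: ScattererSpec, frequency_ghz: float,
                         dirs: DirectionPair) -> np.ndarray:
    """Generalized Rayleigh-Gans amplitude matrix of a slender cylinder, cm."""
    if spec.shape != "cylinder":
        raise ValueError("needle_scattering_rg requires a cylinder spec")
    k = wavenumber(frequency_ghz)
    lam = 2.0 * math.pi / k
    if spec.radius / lam > 0.05:
        warnings.warn(
            "cylinder radius exceeds the slender-cylinder validity threshold "
            "(radius > 0.05 wavelength)", stacklevel=2,
        )
    return _born_amp_grid(spec, k, dirs.ki, dirs.ks, np.asarray(spec.axis))


# ---------------------------------------------------------------------------
# Infinite-length cylinder approximation
# ---------------------------------------------------------------------------

def _orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix R with rows (e1, e2, axis); maps global -> cylinder."""
    a = np.asarray(axis, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, a)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return np.stack([e1, e2, a])


def _cyl_modal_coeffs(eps: complex, a: float, k: float, ci: float,
                      ez0: complex, hz0: complex, phi_i: float,
                      nmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Internal E_z/H_z modal coefficients A_n, B_n, n = -nmax..nmax.

    Solves the four continuity conditions (E_z, H_z, E_phi, H_phi) at the rod
    surface per azimuthal harmonic, for an obliquely incident plane wave with
    axial field components ez0, hz0 (eta0 = 1 units) arriving from azimuth
    phi_i. ci is the cosine of the angle between the incident direction and
    the cylinder axis.
    """
    si2 = 1.0 - ci * ci
    lam0 = k * math.sqrt(max(si2, 1e-30))
    lam1 = k * np.sqrt(eps - ci * ci)
    kz = k * ci
    n = np.arange(-nmax, nmax + 1)

    j1 = special.jv(n, lam1 * a)
    j1p = special.jvp(n, lam1 * a)
    j0 = special.jv(n, lam0 * a)
    j0p = special.jvp(n, lam0 * a)
    h0 = special.hankel1(n, lam0 * a)
    h0p = special.h1vp(n, lam0 * a)

    inc = (1j ** n) * np.exp(-1j * n * phi_i)
    inc_e = ez0 * inc
    inc_h = hz0 * inc

    l1sq = lam1 * lam1
    l0sq = lam0 * lam0
    na_ = 1j * n / a  # in/rho at rho = a

    m = np.zeros((n.size, 4, 4), dtype=complex)
    rhs = np.zeros((n.size, 4), dtype=complex)
    # unknowns x = [A, B, aS, bS]
    # E_z continuity
    m[:, 0, 0] = j1
    m[:, 0, 2] = -h0
    rhs[:, 0] = inc_e * j0
    # H_z continuity
    m[:, 1, 1] = j1
    m[:, 1, 3] = -h0
    rhs[:, 1] = inc_h * j0
    # E_phi = (i/lam^2) [kz (in/rho) E_z - k dH_z/drho]
    m[:, 2, 0] = (kz * na_ * j1) / l1sq
    m[:, 2, 1] = (-k * lam1 * j1p) / l1sq
    m[:, 2, 2] = -(kz * na_ * h0) / l0sq
    m[:, 2, 3] = -(-k * lam0 * h0p) / l0sq
    rhs[:, 2] = (kz * na_ * inc_e * j0 - k * lam0 * inc_h * j0p) / l0sq
    # H_phi = (i/lam^2) [kz (in/rho) H_z + k eps_r dE_z/drho]
    m[:, 3, 0] = (k * eps * lam1 * j1p) / l1sq
    m[:, 3, 1] = (kz * na_ * j1) / l1sq
    m[:, 3, 2] = -(k * lam0 * h0p) / l0sq
    m[:, 3, 3] = -(kz * na_ * h0) / l0sq
    rhs[:, 3] = (kz * na_ * inc_h * j0 + k * lam0 * inc_e * j0p) / l0sq

    try:
        sol = np.linalg.solve(m, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostics
        raise RuntimeError(
            f"cylinder modal system singular (|lam1 a| = {abs(lam1) * a:.3g})"
        ) from exc
    return sol[:, 0], sol[:, 1]


def _lommel(n: np.ndarray, alpha: complex, beta: np.ndarray,
            a: float) -> np.ndarray:
    """Integral_0^a J_n(alpha r) J_n(beta r) r dr, vectorized over (n, beta)."""
    beta = np.asarray(beta, dtype=complex)
    n_ = n[:, None] if beta.ndim else n
    ja = special.jv(n_, alpha * a)
    jap = special.jvp(n_, alpha * a)
    jb = special.jv(n_, beta * a)
    jbp = special.jvp(n_, beta * a)
    den = alpha * alpha - beta * beta
    small = np.abs(den) < 1e-10 * (np.abs(alpha) ** 2 + np.abs(beta) ** 2 + 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = a * (beta * ja * jbp - alpha * jap * jb) / den
    if np.any(small):
        # equal-argument (or nearly) closed form
        x = alpha * a
        eq = (a * a / 2.0) * (jap * jbp + (1.0 - (n_ / x) ** 2) * ja * jb)
        out = np.where(small, eq, out)
    return out


def _nmax_schedule(x1: float, x0: float) -> list[int]:
    base = int(math.ceil(x1 + x0)) + 8
    return [base, base + 8, base + 20, base + 40]


def _cyl_raw_amp(spec: ScattererSpec, k: float, ki: np.ndarray,
                 ks: np.ndarray) -> np.ndarray:
    """Raw (unsymmetrized) finite-length cylinder amplitude.

    ki: single incident direction (3,); ks: scattered directions (..., 3).
    Returns (2, 2) + ks-batch shape.
    """
    eps = spec.eps
    a, length = spec.radius, spec.thickness_or_length
    R = _orthonormal_frame(np.asarray(spec.axis))

    ki_c = R @ np.asarray(ki, float)
    ks_flat = np.asarray(ks, float).reshape(-1, 3) @ R.T
    ci = float(np.clip(ki_c[2], -1.0, 1.0))
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    phi_i = math.atan2(ki_c[1], ki_c[0]) if si > 1e-12 else 0.0
    kz = k * ci
    lam1 = k * np.sqrt(eps - ci * ci)

    vi, hi = pol_basis(ki)
    vs, hs = pol_basis(np.asarray(ks, float))
    vs_flat = vs.reshape(-1, 3)
    hs_flat = hs.reshape(-1, 3)

    cs = np.clip(ks_flat[:, 2], -1.0, 1.0)
    ss = np.sqrt(np.maximum(0.0, 1.0 - cs * cs))
    phi_s = np.arctan2(ks_flat[:, 1], ks_flat[:, 0])
    beta = k * ss

    axial = length * _sinc((kz - k * cs) * length / 2.0)

    coeffs = {}
    for nmax in _nmax_schedule(abs(lam1) * a, k * a):
        n = np.arange(-nmax, nmax + 1)
        converged = True
        for q_idx, ei in enumerate((vi, hi)):
            ei_c = R @ ei
            ez0 = complex(ei_c[2])
            hz0 = complex(np.cross(ki_c, ei_c)[2])
            A, B = _cyl_modal_coeffs(eps, a, k, ci, ez0, hz0, phi_i, nmax)
            coeffs[q_idx] = (A, B)
            # what must decay is the field contribution A_n J_n(lam1 a),
            # not A_n itself (whose incident part has constant magnitude)
            jedge = np.abs(special.jv(np.array([-nmax, nmax]), lam1 * a))
            tail = max(abs(A[0]) * jedge[0], abs(A[-1]) * jedge[1],
                       abs(B[0]) * jedge[0], abs(B[-1]) * jedge[1])
            bulk = max((np.abs(A) * np.abs(special.jv(n, lam1 * a))).max(),
                       (np.abs(B) * np.abs(special.jv(n, lam1 * a))).max(),
                       1e-300)
            if tail > 1e-9 * bulk:
                converged = False
        if converged:
            break
    else:
        raise RuntimeError(
            "cylinder Bessel series did not converge: modal tail still "
            f"significant at nmax = {nmax} (|lam1 a| = {abs(lam1) * a:.3g})"
        )

    q_n = _lommel(n, lam1, beta, a)                      # (nh, nb)
    q_np1 = _lommel(n + 1, lam1, beta, a)
    q_nm1 = _lommel(n - 1, lam1, beta, a)

    phase_n = np.exp(1j * np.outer(n, phi_s))            # (nh, nb)
    c_n = 2.0 * math.pi * ((-1j) ** n)[:, None] * phase_n

    out = np.empty((2, 2, ks_flat.shape[0]), dtype=complex)
    pref = (k * k * (eps - 1.0) / (4.0 * math.pi)) * axial
    for q_idx in (0, 1):
        A, B = coeffs[q_idx]
        gz = np.einsum("n,nb->b", A, c_n * q_n)
        u_plus = (1j / lam1) * (-kz * A + 1j * k * B)
        u_minus = (1j / lam1) * (kz * A + 1j * k * B)
        g_plus = np.einsum(
            "n,nb->b", u_plus, c_n * q_np1 * (-1j) * np.exp(1j * phi_s)[None, :]
        )
        g_minus = np.einsum(
            "n,nb->b", u_minus, c_n * q_nm1 * 1j * np.exp(-1j * phi_s)[None, :]
        )
        gx = 0.5 * (g_plus + g_minus)
        gy = (g_plus - g_minus) / 2j
        g_cyl = np.stack([gx, gy, gz], axis=-1)          # cylinder frame
        g_glob = g_cyl @ R                               # back to global
        out[0, q_idx] = pref * np.einsum("bi,bi->b", vs_flat.astype(complex),
                                         g_glob)
        out[1, q_idx] = pref * np.einsum("bi,bi->b", hs_flat.astype(complex),
                                         g_glob)
    return out.reshape((2, 2) + np.asarray(ks, float).shape[:-1])


_ETA = np.array([[1.0, -1.0], [-1.0, 1.0]])  # reciprocity sign, [p, q]


def cylinder_scattering_infinite(spec: ScattererSpec, frequency_ghz: float,
                                 dirs: DirectionPair) -> np.ndarray:
    """Finite-length cylinder amplitude via the infinite-length approximation.

    The internal field is the exact Bessel-series solution of the obliquely
    illuminated infinite dielectric cylinder, radiated over the finite length
    (truncated radiation integral with sinc axial pattern). The result is
    symmetrized over the reciprocal geometry, restoring the exact reciprocity
    the truncation breaks.
    """
    if spec.shape != "cylinder":
        raise ValueError("cylinder_scattering_infinite requires a cylinder spec")
    if spec.thickness_or_length < 2.0 * spec.radius:
        warnings.warn("cylinder is not elongated (length < diameter)",
                      stacklevel=2)
    k = wavenumber(frequency_ghz)
    fwd = _cyl_raw_amp(spec, k, dirs.ki, dirs.ks)
    rev = _cyl_raw_amp(spec, k, -dirs.ks, -dirs.ki[None, :])[..., 0]
    return 0.5 * (fwd + _ETA * rev.T)


def scattering_amplitude(spec: ScattererSpec, frequency_ghz: float,
                         dirs: DirectionPair) -> np.ndarray:
    """Dispatch to the spec's scattering approximation."""
    if spec.approximation == "physical_optics":
        return disc_scattering_po(spec, frequency_ghz, dirs)
    if spec.approximation == "rayleigh_gans":
        return needle_scattering_rg(spec, frequency_ghz, dirs)
    return cylinder_scattering_infinite(spec, frequency_ghz, dirs)


# ---------------------------------------------------------------------------
# Cross sections
# ---------------------------------------------------------------------------

def _absorption_cross_section(spec: ScattererSpec, k: float,
                              ki: np.ndarray, pol: np.ndarray) -> float:
    """sigma_abs = k eps'' Integral |E_int|^2 dV for unit incident amplitude.

    For the Born-type models this equals the optical theorem applied to the
    forward amplitude (which at this order captures absorption only); for the
    modal cylinder solution the integral is evaluated by radial quadrature
    over the harmonic expansion.
    """
    eps = spec.eps
    if eps.imag == 0.0:
        return 0.0
    axis = np.asarray(spec.axis)
    if spec.approximation in ("physical_optics", "rayleigh_gans"):
        ca = abs(complex(np.dot(pol, axis))) ** 2
        if spec.shape == "disc":
            w = (1.0 - ca) + ca / abs(eps) ** 2
        else:
            w = ca + (1.0 - ca) * abs(2.0 / (eps + 1.0)) ** 2
        return k * eps.imag * spec.volume * w

    a, length = spec.radius, spec.thickness_or_length
    R = _orthonormal_frame(axis)
    ki_c = R @ np.asarray(ki, float)
    ci = float(np.clip(ki_c[2], -1.0, 1.0))
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    phi_i = math.atan2(ki_c[1], ki_c[0]) if si > 1e-12 else 0.0
    lam1 = k * np.sqrt(eps - ci * ci)
    kz = k * ci
    nmax = int(math.ceil(abs(lam1) * a + k * a)) + 8
    nn = np.arange(-nmax, nmax + 1)
    ei_c = R @ np.asarray(pol, float)
    A, B = _cyl_modal_coeffs(eps, a, k, ci, complex(ei_c[2]),
                             complex(np.cross(ki_c, ei_c)[2]), phi_i, nmax)
    x, wq = np.polynomial.legendre.leggauss(64)
    rho = 0.5 * a * (x + 1.0)
    wr = 0.5 * a * wq * rho
    jz = special.jv(nn[:, None], lam1 * rho[None, :])
    jp1 = special.jv(nn[:, None] + 1, lam1 * rho[None, :])
    jm1 = special.jv(nn[:, None] - 1, lam1 * rho[None, :])
    u_plus = (1j / lam1) * (-kz * A + 1j * k * B)
    u_minus = (1j / lam1) * (kz * A + 1j * k * B)
    dens = (np.abs(A[:, None] * jz) ** 2
            + 0.5 * np.abs(u_plus[:, None] * jp1) ** 2
            + 0.5 * np.abs(u_minus[:, None] * jm1) ** 2)
    integral = 2.0 * math.pi * float(np.sum(dens @ wr))
    return k * eps.imag * length * integral


def _scattering_cross_section(spec: ScattererSpec, frequency_ghz: float,
                              ki: np.ndarray, pol_index: int,
                              n_theta: int = 32, n_phi: int = 32) -> float:
    """Integrated bistatic cross section over the full sphere, cm^2."""
    k = wavenumber(frequency_ghz)
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = 2.0 * math.pi * (np.arange(n_phi) + 0.5) / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    ks = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                   np.cos(tt)], axis=-1)
    if spec.approximation == "infinite_cylinder":
        amp = _cyl_raw_amp(spec, k, ki, ks)
    else:
        amp = _born_amp_grid(spec, k, ki, ks, np.asarray(spec.axis))
    total = np.abs(amp[0, pol_index]) ** 2 + np.abs(amp[1, pol_index]) ** 2
    return float(np.sum(total * w[:, None]) * (2.0 * math.pi / n_phi))


def extinction_cross_section(spec: ScattererSpec, frequency_ghz: float,
                             theta_i: float, pol: str,
                             phi_i: float = 0.0) -> float:
    """Extinction cross section (cm^2) for a given incident direction.

    Computed as absorption plus integrated scattering. The optical theorem
    applied to the forward amplitude of these internal-field approximations
    recovers only the absorptive part (the scattered power is of second order
    in the contrast), so the scattering part is added explicitly by angular
    quadrature; this keeps extinction >= absorption and makes a lossless
    scatterer's extinction equal its total scattering cross section.
    """
    ki = direction(theta_i, phi_i)
    vi, hi = pol_basis(ki)
    p = _POLS.index(pol.lower())
    e = (vi, hi)[p]
    k = wavenumber(frequency_ghz)
    return (_absorption_cross_section(spec, k, ki, e)
            + _scattering_cross_section(spec, frequency_ghz, ki, p))


# ---------------------------------------------------------------------------
# Angular-grid kernels and layer phase matrices
# ---------------------------------------------------------------------------

@dataclass
class SpeciesKernels:
    """Single-scatterer |F|^2 couplings and cross sections on an angular grid.

    ``pk[p_s, p_i, h_s, h_i, k_s, k_i, l]`` is the bistatic scattering cross
    section per unit solid angle (cm^2/sr) from incident state
    (hemisphere h_i, zenith node k_i, polarization p_i) to scattered state at
    azimuth difference 2 pi l / n_azimuth. Hemisphere 0 is up-going.
    ``sig_a[p_i, h_i, k_i]`` is the absorption cross section (cm^2) and
    ``sig_e`` the extinction cross section with the scattering part summed on
    this same grid, so that layer operators built from these kernels conserve
    energy to the grid's own quadrature accuracy.
    """

    pk: np.ndarray
    sig_a: np.ndarray
    sig_e: np.ndarray
    frequency_ghz: float
    name: str = ""


def _grid_directions(grid) -> np.ndarray:
    """Direction vectors d[h, k, l, :] for the grid's states."""
    mu = grid.mu
    nz, na = mu.size, grid.n_azimuth
    phi = 2.0 * math.pi * np.arange(na) / na
    st = np.sqrt(1.0 - mu ** 2)
    d = np.empty((2, nz, na, 3))
    for h, sign in enumerate((1.0, -1.0)):
        d[h, ..., 0] = st[:, None] * np.cos(phi)[None, :]
        d[h, ..., 1] = st[:, None] * np.sin(phi)[None, :]
        d[h, ..., 2] = sign * mu[:, None]
    return d


def species_kernels(spec: ScattererSpec, frequency_ghz: float, grid,
                    n_orient: int = 12) -> SpeciesKernels:
    """Evaluate a species' scattering kernels on an angular grid.

    For ``randomize_azimuth`` species the kernels are the mean of |F|^2 over
    ``n_orient`` equispaced in-plane axis orientations, which restores the
    azimuthal symmetry the doubling grid assumes.
    """
    k = wavenumber(frequency_ghz)
    nz, na = grid.mu.size, grid.n_azimuth
    dirs = _grid_directions(grid)
    ki_set = dirs[:, :, 0, :]                       # incident at phi = 0
    ks_set = dirs                                   # scattered at phi = dphi

    if spec.randomize_azimuth:
        base = np.asarray(spec.axis)
        if abs(base[2]) > 1e-9:
            raise ValueError("randomize_azimuth requires a horizontal axis")
        angles = 2.0 * math.pi * (np.arange(n_orient) + 0.5) / n_orient
        axes = [np.array([math.cos(t), math.sin(t), 0.0]) for t in angles]
    else:
        axes = [np.asarray(spec.axis)]

    pk = np.zeros((2, 2, 2, 2, nz, nz, na))
    sig_a = np.zeros((2, 2, nz))
    ks_flat = ks_set.reshape(-1, 3)

    for axis in axes:
        for h_i in range(2):
            for k_i in range(nz):
                ki = ki_set[h_i, k_i]
                if spec.approximation == "infinite_cylinder":
                    spec_ax = ScattererSpec(
                        spec.shape, spec.radius, spec.thickness_or_length,
                        spec.permittivity, spec.approximation,
                        tuple(axis), False, spec.name,
                    )
                    amp = _cyl_raw_amp(spec_ax, k, ki, ks_flat)
                else:
                    amp = _born_amp_grid(spec, k, ki[None, :], ks_flat, axis)
                amp = amp.reshape(2, 2, 2, nz, na)
                pk[:, :, :, h_i, :, k_i, :] += np.abs(amp) ** 2
                vi, hi_v = pol_basis(ki)
                for p_i, e in enumerate((vi, hi_v)):
                    if spec.approximation == "infinite_cylinder":
                        sig_a[p_i, h_i, k_i] += _absorption_cross_section(
                            spec_ax, k, ki, e)
                    else:
                        sig_a[p_i, h_i, k_i] += _absorption_cross_section(
                            spec, k, ki, e)
    pk /= len(axes)
    sig_a /= len(axes)

    if spec.approximation == "infinite_cylinder":
        pk = _symmetrize_kernel(pk)

    # grid-consistent scattering cross section: quadrature of pk over the
    # scattered sphere for each incident state
    dphi_w = 2.0 * math.pi / na
    sig_s = np.einsum("pqsikml,k->qim", pk, grid.w) * dphi_w
    sig_e = sig_a + sig_s
    return SpeciesKernels(pk=pk, sig_a=sig_a, sig_e=sig_e,
                          frequency_ghz=frequency_ghz, name=spec.name)


def _symmetrize_kernel(pk: np.ndarray) -> np.ndarray:
    """Average |F|^2 kernels with their reciprocal-geometry counterparts.

    Reciprocity maps (p, q, h_s, h_i, k_s, k_i, l) to
    (q, p, 1-h_i, 1-h_s, k_i, k_s, -l); |F|^2 is invariant up to the
    truncation error of the infinite-length approximation, which this
    averaging removes.
    """
    rev = pk.transpose(1, 0, 3, 2, 5, 4, 6)[:, :, ::-1, ::-1]
    rev = np.concatenate([rev[..., :1], rev[..., :0:-1]], axis=-1)
    return 0.5 * (pk + rev)


@dataclass
class PhaseField:
    """Per-unit-volume phase matrix and extinction of a layer's medium.

    ``p[p_s, p_i, h_s, h_i, k_s, k_i, l]`` in cm^-1 sr^-1;
    ``kappa[p_i, h_i, k_i]`` in cm^-1.
    """

    p: np.ndarray
    kappa: np.ndarray


def layer_phase_matrix(number_densities, kernels) -> PhaseField:
    """Incoherent phase matrix of a mixture: sum of density * |F|^2 kernels.

    ``number_densities`` are per-species volume number densities in cm^-3
    (linear in each; fractional values are fine). Species lists must match.
    """
    densities = list(number_densities)
    kerns = list(kernels)
    if len(densities) != len(kerns):
        raise ValueError("one number density per species kernel is required")
    if not kerns:
        raise ValueError("at least one species is required")
    for nd in densities:
        if nd < 0:
            raise ValueError("number densities must be nonnegative")
    p = sum(nd * kk.pk for nd, kk in zip(densities, kerns))
    kappa = sum(nd * kk.sig_e for nd, kk in zip(densities, kerns))
    return PhaseField(p=np.asarray(p, float), kappa=np.asarray(kappa, float))
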