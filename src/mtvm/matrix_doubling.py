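"""Matrix Doubling Algorithm for a layered scattering canopy.

The vector radiative transfer equation is solved numerically by slicing the
canopy into thin horizontal slabs, building each slab's backward/forward
scattering operators from its phase matrix, and combining adjacent slabs with
the matrix geometric series that sums every order of inter-slab multiple
scattering.

Discretization. Specific intensity is sampled on a product grid of zenith
quadrature nodes mu_k = cos(theta_k) (Gauss-Legendre on (0,1), optionally
adjusted so the radar incidence cosine is an exact node), an equispaced
azimuth-difference grid (the medium is azimuthally symmetric, so operators
depend on phi_s - phi_i only and are block-circulant in azimuth), and the
two linear polarizations (v, h) carried as incoherent intensities. A layer's
operators are stored as real kernels ``K[l, i_out, i_in]`` over the azimuth
difference index l, with flattened state index ``i = 2 k + pol`` per
hemisphere.

A thin slab of thickness dz with per-volume phase matrix P and extinction
kappa has

    S  = U^-1 P_backward dz  (quadrature weights applied),
    T  = D + U^-1 P_forward dz,     D = diag(exp(-kappa dz / mu_k)),

where U = diag(mu_k) so U^-1 applies the 1/cos(theta) slant-path factor. The
direct attenuated term D is included in T: without it the doubling neither
conserves energy nor reproduces Beer-Lambert attenuation. Two stacked slabs
(1 on the incident side, i.e. on top) combine as

    S  = S1 + T1* S2 (I - S1* S2)^-1 T1
    T  = T2 (I - S1* S2)^-1 T1
    S* = S2* + T2 S1* (I - S2 S1*)^-1 T2*
    T* = T1* (I - S2 S1*)^-1 T2*

(the geometric series over bounce orders). Starred operators are for
incidence from below. Combination is performed per azimuth Fourier harmonic,
where the block-circulant operators diagonalize.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .scatterer_models import PhaseField

__all__ = [
    "AngularGrid",
    "LayerOperators",
    "SigmaZero",
    "thin_layer_operators",
    "combine_layers",
    "stack_canopy",
    "stack_uniform",
    "backscatter_sigma0",
    "power_balance",
]

_POLS = ("v", "h")


@dataclass(frozen=True)
class AngularGrid:
    """Quadrature over propagation directions.

    ``mu`` are zenith cosines in (0, 1) shared by both hemispheres, with
    weights ``w`` normalized so sum(w) = 1 per hemisphere; azimuth uses
    ``n_azimuth`` equispaced nodes of weight 2 pi / n_azimuth.
    """

    mu: np.ndarray
    w: np.ndarray
    n_azimuth: int
    theta_inc_deg: float | None = None

    def __post_init__(self) -> None:
        if self.n_azimuth % 2:
            raise ValueError("n_azimuth must be even (backscatter needs "
                             "an azimuth-difference node at pi)")
        if np.any(self.mu <= 0) or np.any(self.mu >= 1):
            raise ValueError("zenith cosines must lie strictly inside (0, 1)")
        if np.any(self.w <= 0):
            raise ValueError("quadrature weights must be positive")

    @classmethod
    def build(cls, n_zenith: int = 8, n_azimuth: int = 16,
              theta_inc_deg: float | None = 43.0) -> "AngularGrid":
        """Gauss-Legendre zenith grid, adjusted to contain the incidence node.

        When ``theta_inc_deg`` is given, the Gauss-Legendre node closest to
        cos(theta_inc) is replaced by it and the weights are recomputed from
        the polynomial moment conditions on (0, 1) (exactness degree drops
        from 2n-1 to n-1, which the doubling does not need).
        """
        x, w = np.polynomial.legendre.leggauss(n_zenith)
        mu = 0.5 * (x + 1.0)
        w = 0.5 * w
        if theta_inc_deg is not None:
            mu0 = math.cos(math.radians(theta_inc_deg))
            mu = mu.copy()
            mu[np.argmin(np.abs(mu - mu0))] = mu0
            powers = np.vander(mu, n_zenith, increasing=True).T
            moments = 1.0 / (1.0 + np.arange(n_zenith))
            w = np.linalg.solve(powers, moments)
            if np.any(w <= 0):
                raise ValueError(
                    "weight recomputation produced nonpositive weights; "
                    "choose a different n_zenith"
                )
        return cls(mu=mu, w=w, n_azimuth=n_azimuth,
                   theta_inc_deg=theta_inc_deg)

    @property
    def n_states(self) -> int:
        """States per hemisphere per azimuth node (zenith x polarization)."""
        return 2 * self.mu.size

    def node_index(self, theta_deg: float) -> int:
        mu0 = math.cos(math.radians(theta_deg))
        idx = int(np.argmin(np.abs(self.mu - mu0)))
        if abs(self.mu[idx] - mu0) > 1e-9:
            raise ValueError(
                f"incidence {theta_deg} deg is not a grid node; build the "
                "grid with theta_inc_deg set accordingly"
            )
        return idx


@dataclass
class LayerOperators:
    """Backward/forward scattering operators of a slab.

    ``S`` reflects down-going intensity up, ``T`` transmits down-going
    intensity down; starred operators are for incidence from below. Arrays
    have shape (n_azimuth, n, n) over the azimuth-difference grid.
    """

    S: np.ndarray
    T: np.ndarray
    S_star: np.ndarray
    T_star: np.ndarray
    dz: float

    @classmethod
    def vacuum(cls, n: int, n_azimuth: int) -> "LayerOperators":
        z = np.zeros((n_azimuth, n, n))
        t = z.copy()
        t[0] = np.eye(n)
        return cls(S=z.copy(), T=t.copy(), S_star=z.copy(), T_star=t.copy(),
                   dz=0.0)

    def _harmonic(self) -> "_HarmonicOps":
        return _HarmonicOps(
            np.fft.fft(self.S, axis=0), np.fft.fft(self.T, axis=0),
            np.fft.fft(self.S_star, axis=0), np.fft.fft(self.T_star, axis=0),
            self.dz,
        )


@dataclass
class _HarmonicOps:
    """Layer operators in the azimuth Fourier domain (internal)."""

    S: np.ndarray
    T: np.ndarray
    S_star: np.ndarray
    T_star: np.ndarray
    dz: float

    def to_layer(self) -> LayerOperators:
        def back(a: np.ndarray) -> np.ndarray:
            k = np.fft.ifft(a, axis=0)
            return np.ascontiguousarray(k.real)

        return LayerOperators(back(self.S), back(self.T), back(self.S_star),
                              back(self.T_star), self.dz)


@dataclass(frozen=True)
class SigmaZero:
    """A backscattering coefficient sample."""

    channel: str
    value_db: float
    theta_inc_deg: float

    @property
    def linear(self) -> float:
        return 10.0 ** (self.value_db / 10.0) if math.isfinite(self.value_db) \
            else 0.0


def thin_layer_operators(phase: PhaseField, dz: float,
                         grid: AngularGrid) -> LayerOperators:
    """Build a thin slab's operators from its phase matrix and extinction.

    The scattered parts are first order in dz (linear); the direct term is
    the exact Beer-Lambert diagonal. Warns when the slab's single-pass
    optical thickness kappa dz / mu_min exceeds 0.1.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if not np.all(np.isfinite(phase.p)) or not np.all(np.isfinite(phase.kappa)):
        raise ValueError("phase field contains non-finite entries")
    nz, na = grid.mu.size, grid.n_azimuth
    n = 2 * nz
    tau_max = float(np.max(phase.kappa) * dz / grid.mu.min())
    if tau_max > 0.1:
        warnings.warn(
            f"thin-layer precondition violated: max kappa dz/mu = "
            f"{tau_max:.3f} > 0.1; reduce dz", stacklevel=2,
        )

    dphi_w = 2.0 * math.pi / na
    inv_mu = 1.0 / grid.mu

    def block(h_s: int, h_i: int) -> np.ndarray:
        # p[p_s,p_i,h_s,h_i,k_s,k_i,l] -> K[l, 2*k_s+p_s, 2*k_i+p_i]
        blk = phase.p[:, :, h_s, h_i]                      # (2,2,nz,nz,na)
        blk = blk * inv_mu[None, None, :, None, None]
        blk = blk * grid.w[None, None, None, :, None]
        blk = blk * (dz * dphi_w)
        return np.ascontiguousarray(
            blk.transpose(4, 2, 0, 3, 1).reshape(na, n, n)
        )

    s = block(0, 1)
    t = block(1, 1)
    s_star = block(1, 0)
    t_star = block(0, 0)
    for h, target in ((1, t), (0, t_star)):
        kap = phase.kappa[:, h, :]                          # (2, nz)
        d = np.exp(-kap.T.reshape(n) * dz * np.repeat(inv_mu, 2))
        target[0][np.arange(n), np.arange(n)] += d
    return LayerOperators(S=s, T=t, S_star=s_star, T_star=t_star, dz=dz)


def _combine_h(a: _HarmonicOps, b: _HarmonicOps) -> _HarmonicOps:
    """Combine two slabs (a on the incident side / top) per harmonic."""
    eye = np.eye(a.S.shape[-1])
    try:
        x = np.linalg.solve(eye - a.S_star @ b.S, a.T)
        y = np.linalg.solve(eye - b.S @ a.S_star, b.T_star)
    except np.linalg.LinAlgError as exc:
        rho = max(
            np.abs(np.linalg.eigvals(a.S_star @ b.S)).max(axis=-1).max(),
            np.abs(np.linalg.eigvals(b.S @ a.S_star)).max(axis=-1).max(),
        )
        raise RuntimeError(
            "inter-layer multiple-scattering series diverges: spectral "
            f"radius of S1* S2 is {rho:.6g} (must be < 1)"
        ) from exc
    return _HarmonicOps(
        S=a.S + a.T_star @ b.S @ x,
        T=b.T @ x,
        S_star=b.S_star + b.T @ a.S_star @ y,
        T_star=a.T_star @ y,
        dz=a.dz + b.dz,
    )


def combine_layers(upper: LayerOperators, lower: LayerOperators) -> LayerOperators:
    """Combine two slabs; ``upper`` faces the incident radiation."""
    if upper.S.shape != lower.S.shape:
        raise ValueError("layer operators live on incompatible grids")
    return _combine_h(upper._harmonic(), lower._harmonic()).to_layer()


def stack_canopy(layers: list[LayerOperators]) -> LayerOperators:
    """Sequentially combine a bottom-up list of slabs into one medium.

    ``layers[0]`` is the lowest slab. Combination runs top-down so that the
    accumulated medium always faces the incident radiation; by associativity
    any ordering gives the same result.
    """
    if not layers:
        raise ValueError("at least one layer is required")
    total = layers[-1]._harmonic()
    for lay in layers[-2::-1]:
        total = _combine_h(total, lay._harmonic())
    return total.to_layer()


def stack_uniform(layer: LayerOperators, count: int) -> LayerOperators:
    """Stack ``count`` identical slabs by binary doubling (2^k composition)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    base = layer._harmonic()
    total = None
    while count:
        if count & 1:
            total = base if total is None else _combine_h(total, base)
        count >>= 1
        if count:
            base = _combine_h(base, base)
    return total.to_layer()


def backscatter_sigma0(total: LayerOperators, theta_inc_deg: float,
                       channel: str, grid: AngularGrid) -> SigmaZero:
    """Extract the backscattering coefficient from a stacked medium.

    sigma0_pq = 4 pi cos(theta_i) S[(theta_i, p), (theta_i, q)] at azimuth
    difference pi, divided by the input state's quadrature weight, in dB. An
    empty canopy returns the -inf sentinel.
    """
    k0 = grid.node_index(theta_inc_deg)
    ch = channel.upper()
    if len(ch) != 2 or any(c not in "VH" for c in ch):
        raise ValueError(f"unknown channel {channel!r}")
    p = "VH".index(ch[0])   # received (scattered)
    q = "VH".index(ch[1])   # transmitted (incident)
    l_back = grid.n_azimuth // 2
    elem = float(total.S[l_back, 2 * k0 + p, 2 * k0 + q])
    mu0 = grid.mu[k0]
    weight = grid.w[k0] * (2.0 * math.pi / grid.n_azimuth)
    lin = 4.0 * math.pi * mu0 * elem / weight
    value = 10.0 * math.log10(lin) if lin > 0 else -math.inf
    return SigmaZero(channel=ch, value_db=value, theta_inc_deg=theta_inc_deg)


def power_balance(ops: LayerOperators, grid: AngularGrid) -> np.ndarray:
    """Outgoing/incoming power ratio per down-going input state.

    Power in state (k, pol) at one azimuth node is mu_k w_k dphi I; the ratio
    sums reflected (S) and transmitted (T) output over all output states.
    For a passive layer every entry is <= 1 (equality only without
    absorption and with exact angular quadrature).
    """
    n = grid.n_states
    mu_w = (grid.mu * grid.w).repeat(2)
    out_weight = mu_w[None, :, None]             # over output states
    tot = ((ops.S + ops.T) * out_weight).sum(axis=(0, 1))
    return tot / mu_w
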