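"""Crown envelope geometry.

A crown envelope is a surface of revolution rho(h) bounding the region of a
single plant's scattering components, for h in [0, H]. All envelopes here are
members of one two-parameter family: the squared radius is a quadratic in the
normalized height u = h/H,

    rho^2(h) = (H tan(alpha))^2 * (a u^2 + b u + c),

with alpha the cone half-angle (default 45 deg). The constant c is always
re-derived from the equal-volume constraint

    pi * Integral_0^H rho^2 dh = (pi/3) tan^2(alpha) H^3,

i.e. every envelope encloses the same volume as the reference cone of the
same height, which in normalized units reads a/3 + b/2 + c = 1/3. The four
named shapes are exact members of the family:

    cylinder       (a, b, c) = ( 0,  0, 1/3)
    cone           (a, b, c) = ( 1, -2, 1)
    inverted_cone  (a, b, c) = ( 1,  0, 0)
    ellipsoid      (a, b, c) = (-2,  2, 0)

Normalizing by H and H tan(alpha) makes the printed coefficient triples for
(H = 1, alpha = 45 deg) apply verbatim at any height; physical units (cm) are
restored on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "CrownEnvelope",
    "LayerSlice",
    "NAMED_SHAPES",
    "solve_constraint_c",
    "feasible",
    "envelope_radius",
    "envelope_volume",
    "slice_layers",
    "layer_scatterer_count",
    "lower_half_metrics",
]

#: (a, b) pairs of the named shapes in normalized coordinates; c follows from
#: the equal-volume constraint.
NAMED_SHAPES: dict[str, tuple[float, float]] = {
    "cylinder": (0.0, 0.0),
    "cone": (1.0, -2.0),
    "inverted_cone": (1.0, 0.0),
    "ellipsoid": (-2.0, 2.0),
}

_FEAS_TOL = 1e-9


def solve_constraint_c(a: float, b: float, H: float = 1.0,
                       alpha: float = math.pi / 4) -> float:
    """Solve the equal-volume constraint for the constant coefficient c.

    In the normalized parabola coordinates the constraint is linear,
    a/3 + b/2 + c = 1/3, independent of H and alpha (both cancel under the
    normalization); the signature keeps them for interface symmetry with the
    physical-units constraint.
    """
    if H <= 0:
        raise ValueError("H must be positive")
    # single division keeps the named-shape triples exact in floating point
    return (1.0 - a - 1.5 * b) / 3.0


def feasible(a: float, b: float, c: float, H: float = 1.0) -> bool:
    """True iff a u^2 + b u + c >= 0 on all of [0, 1] (u = h/H).

    Checked analytically: endpoint values plus the interior vertex of the
    quadratic. Boundary cases (the quadratic touching zero, as the cone,
    inverted cone and ellipsoid do) count as feasible.
    """
    q0 = c
    q1 = a + b + c
    if q0 < -_FEAS_TOL or q1 < -_FEAS_TOL:
        return False
    if a > 0:
        u_v = -b / (2.0 * a)
        if 0.0 < u_v < 1.0:
            q_v = c - b * b / (4.0 * a)
            if q_v < -_FEAS_TOL:
                return False
    return True


@dataclass(frozen=True)
class CrownEnvelope:
    """A volume-constrained crown envelope surface of revolution.

    Parameters
    ----------
    kind
        One of the named shapes, or ``"parabolic"`` for a general (a, b)
        member of the family.
    H
        Crown height, cm.
    alpha
        Cone half-angle, radians (default pi/4).
    a, b
        Normalized squared-radius parabola coefficients (required for
        ``kind="parabolic"``; ignored otherwise).
    """

    kind: str = "cylinder"
    H: float = 100.0
    alpha: float = math.pi / 4
    a: float | None = None
    b: float | None = None
    _abc: tuple[float, float, float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise ValueError("crown height H must be positive")
        if self.kind in NAMED_SHAPES:
            a, b = NAMED_SHAPES[self.kind]
        elif self.kind == "parabolic":
            if self.a is None or self.b is None:
                raise ValueError("parabolic envelopes need explicit a and b")
            a, b = float(self.a), float(self.b)
        else:
            raise NotImplementedError(
                f"unknown envelope kind {self.kind!r}; azimuthally asymmetric "
                "envelopes F(phi, h) are not implemented"
            )
        c = solve_constraint_c(a, b)
        if not feasible(a, b, c):
            raise ValueError(
                f"infeasible parabola (a={a}, b={b}, c={c:.6g}): squared "
                "radius goes negative inside [0, H]"
            )
        object.__setattr__(self, "_abc", (a, b, c))

    @property
    def abc(self) -> tuple[float, float, float]:
        """Normalized (a, b, c) triple of the squared-radius parabola."""
        return self._abc

    @property
    def max_radius(self) -> float:
        """Largest rho(h) over the crown, cm."""
        a, b, c = self._abc
        cand = [c, a + b + c]
        if a < 0 and 0.0 < -b / (2 * a) < 1.0:
            cand.append(c - b * b / (4 * a))
        return self.H * math.tan(self.alpha) * math.sqrt(max(cand))

    def sq_radius_norm(self, u):
        """Normalized squared radius q(u) = a u^2 + b u + c."""
        a, b, c = self._abc
        u = np.asarray(u, dtype=float)
        return (a * u + b) * u + c

    def sq_radius_integral(self, h_lo: float, h_hi: float) -> float:
        """Closed-form Integral_{h_lo}^{h_hi} rho^2(z) dz in cm^3."""
        a, b, c = self._abc
        H, t = self.H, math.tan(self.alpha)

        def antideriv(u: float) -> float:
            return ((a / 3.0 * u + b / 2.0) * u + c) * u

        u1, u2 = h_lo / H, h_hi / H
        return (H * t) ** 2 * H * (antideriv(u2) - antideriv(u1))


def envelope_radius(envelope: CrownEnvelope, h: float) -> float:
    """rho(h) in cm; h must lie in [0, H]."""
    if not 0.0 <= h <= envelope.H:
        raise ValueError(f"h={h} outside [0, {envelope.H}]")
    q = float(envelope.sq_radius_norm(h / envelope.H))
    q = max(q, 0.0)  # boundary shapes touch zero; guard rounding
    return envelope.H * math.tan(envelope.alpha) * math.sqrt(q)


def envelope_volume(envelope: CrownEnvelope) -> float:
    """pi * Integral_0^H rho^2 dh, cm^3 (closed form)."""
    return math.pi * envelope.sq_radius_integral(0.0, envelope.H)


@dataclass(frozen=True)
class LayerSlice:
    """One horizontal slab of a crown envelope."""

    h_lo: float
    h_hi: float
    sq_radius_integral: float  # Integral rho^2 dz over the slab, cm^3

    @property
    def thickness(self) -> float:
        return self.h_hi - self.h_lo


def slice_layers(envelope: CrownEnvelope, dz: float) -> list[LayerSlice]:
    """Slice the crown into slabs of thickness dz, bottom-up.

    The slabs cover [0, H] exactly; every slab has thickness dz except a
    possibly thinner final slab when H is not a multiple of dz.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if dz > envelope.H:
        raise ValueError("dz must not exceed the crown height")
    edges = [i * dz for i in range(int(math.ceil(envelope.H / dz - 1e-12)))]
    edges.append(envelope.H)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        out.append(LayerSlice(lo, hi, envelope.sq_radius_integral(lo, hi)))
    return out


def layer_scatterer_count(envelope: CrownEnvelope, mu_j: float,
                          layer: LayerSlice) -> float:
    """Expected scatterer count N_j = pi * mu_j * Integral rho^2 dz.

    mu_j is the species volume density in cm^-3. The count is returned as a
    nonnegative real; fractional counts are meaningful for the radiative
    transfer path (the 3D instantiation rounds separately).
    """
    if mu_j < 0:
        raise ValueError("volume density must be nonnegative")
    return math.pi * mu_j * layer.sq_radius_integral


def lower_half_metrics(envelope: CrownEnvelope) -> dict[str, float]:
    """Lower-half concentration metrics of the crown.

    Returns ``volume_fraction`` (share of the crown volume below H/2) and
    ``radius_profile_fraction`` (share of Integral rho dh below H/2). For the
    four named shapes the radius-profile fractions are exactly 50/75/25/50 %
    (cylinder/cone/inverted cone/ellipsoid) while the true volume fractions
    are 1/2, 7/8, 1/8 and 1/2; both are exposed because the two metrics are
    easily conflated.
    """
    vol_lo = envelope.sq_radius_integral(0.0, envelope.H / 2.0)
    vol = envelope.sq_radius_integral(0.0, envelope.H)

    def rho_norm(u: float) -> float:
        return math.sqrt(max(0.0, float(envelope.sq_radius_norm(u))))

    r_lo, _ = quad(rho_norm, 0.0, 0.5, limit=200)
    r_hi, _ = quad(rho_norm, 0.5, 1.0, limit=200)
    return {
        "volume_fraction": vol_lo / vol,
        "radius_profile_fraction": r_lo / (r_lo + r_hi),
    }
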