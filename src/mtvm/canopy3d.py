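"""Explicit 3D canopy instantiation and geometry export.

Builds a seeded, collision-free arrangement of geometric primitives (discs
and cylinders) inside a crown envelope, mirroring the construction used to
feed full-wave electromagnetic solvers: the crown is divided into Nl layers
of equal thickness, each layer receives a component count proportional to
its exact slab volume (equal counts for the cylinder crown), vertical
stalks/branches are placed uniformly over the layer's cross-section by
rejection sampling, and every leaf is attached at a random height and
azimuth to the surface of a randomly chosen stalk (or branch) of its layer.

Coordinates: z = h measured up from the crown base (the inverted cone's apex
is at z = 0), with the envelope axis at x = y = 0. Layers are indexed
bottom-up (index 0 at the base); only labeling, not geometry, depends on
this choice.

Containment is enforced on each primitive's anchor point (its center): the
envelope bounds where components are rooted, and bodies of finite extent may
protrude beyond the mathematical surface, as real foliage does around an
idealized crown. With the tabulated component lengths this is the only
feasible reading: near the cone or ellipsoid apexes a region thinner than a
stalk/branch length must still host its planned component count, which
strict whole-body containment makes geometrically impossible.

Collision detection treats every primitive as a finite cylinder (a disc is
a thin cylinder along its normal) and tests segment-segment distance
against the radius sum; tangency (leaf touching its parent stalk) is not an
intersection (strict overlap test with 1e-9 cm slack).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .crown_geometry import CrownEnvelope
from .scatterer_models import ScattererSpec

__all__ = [
    "Primitive",
    "LayerPlan",
    "Canopy3D",
    "ValidationReport",
    "layer_count_3d",
    "plan_layers",
    "place_components",
    "validate_canopy",
    "export_geometry",
    "write_manifest",
    "read_manifest",
]

_OVERLAP_SLACK = 1e-9
_CONTAIN_TOL = 1e-6


@dataclass(frozen=True)
class Primitive:
    """One geometric component: a disc or a finite cylinder."""

    kind: str                       # 'disc' | 'cylinder'
    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    length: float                   # thickness for discs

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "cylinder"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("primitive dimensions must be positive")
        n = math.sqrt(sum(a * a for a in self.axis))
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            object.__setattr__(self, "axis",
                               tuple(a / n for a in self.axis))

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        a = np.asarray(self.axis)
        h = 0.5 * self.length
        return c - h * a, c + h * a


@dataclass(frozen=True)
class LayerPlan:
    """Planned content of one horizontal layer (bottom-up index)."""

    index: int
    z_lo: float
    z_hi: float
    volume: float        # exact slab volume pi * Int rho^2 dz, cm^3
    count: int           # components per species in this layer
    radius_lo: float     # envelope radius at the slab faces, cm
    radius_hi: float
    volume_cumulative: float


def layer_count_3d(H: float, component_length: float, canopy: str) -> int:
    """Number of layers: floor(H/l + 0.5) for canopy A, floor(H/l) for B."""
    if H <= 0 or component_length <= 0:
        raise ValueError("H and component length must be positive")
    if H < component_length:
        raise ValueError("crown height below component length: no complete "
                         "layer fits")
    ratio = H / component_length
    c = canopy.upper()
    if c == "A":
        return int(math.floor(ratio + 0.5))
    if c == "B":
        return int(math.floor(ratio))
    raise ValueError(f"unknown canopy {canopy!r}")


def plan_layers(envelope: CrownEnvelope, rho_v: float,
                n_layers: int) -> list[LayerPlan]:
    """Per-layer component counts from exact slab volumes.

    The cylinder crown gets equal counts ceil(rho_v * V / Nl) in every
    layer; the shaped crowns get ceil(rho_v * V_i) with V_i the exact
    integral of pi rho^2 over the slab (the closed form replaces the
    recursive slab approximations, so the slab volumes sum to the envelope
    volume exactly).
    """
    if n_layers < 1:
        raise ValueError("at least one layer is required")
    if rho_v < 0:
        raise ValueError("rho_v must be nonnegative")
    H = envelope.H
    dz = H / n_layers
    total = math.pi * envelope.sq_radius_integral(0.0, H)
    plans = []
    cum = 0.0
    for i in range(n_layers):
        z_lo, z_hi = i * dz, min((i + 1) * dz, H)
        vol = math.pi * envelope.sq_radius_integral(z_lo, z_hi)
        cum += vol
        if envelope.kind == "cylinder":
            count = math.ceil(rho_v * total / n_layers - 1e-12)
        else:
            count = math.ceil(rho_v * vol - 1e-12)
        from .crown_geometry import envelope_radius

        plans.append(LayerPlan(
            index=i, z_lo=z_lo, z_hi=z_hi, volume=vol, count=int(count),
            radius_lo=envelope_radius(envelope, z_lo),
            radius_hi=envelope_radius(envelope, z_hi),
            volume_cumulative=cum,
        ))
    return plans


@dataclass
class Canopy3D:
    """A placed, collision-free 3D canopy."""

    envelope: CrownEnvelope
    primitives: list[Primitive]
    seed: int
    layer_counts: list[int] = field(default_factory=list)
    attempts: int = 0


# ---------------------------------------------------------------------------
# geometry predicates
# ---------------------------------------------------------------------------

def _segment_arrays(prims: list[Primitive]):
    if not prims:
        return (np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0))
    p0 = np.array([p.endpoints[0] for p in prims])
    p1 = np.array([p.endpoints[1] for p in prims])
    r = np.array([p.radius for p in prims])
    return p0, p1, r


def segment_distance(p0: np.ndarray, p1: np.ndarray, q0: np.ndarray,
                     q1: np.ndarray) -> np.ndarray:
    """Minimum distance between segment (p0, p1) and segments (q0, q1).

    p0/p1 are single points (3,); q0/q1 may be arrays (m, 3). Standard
    clamped closest-point computation.
    """
    q0 = np.atleast_2d(q0)
    q1 = np.atleast_2d(q1)
    d1 = p1 - p0                      # direction of segment 1 (3,)
    d2 = q1 - q0                      # directions of segments 2 (m, 3)
    r = p0[None, :] - q0
    a = float(np.dot(d1, d1))
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("j,ij->i", d1, d2)
    c = np.einsum("j,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    s = np.where(denom > 1e-14,
                 np.clip((b * f - c * e) / np.where(denom > 1e-14, denom, 1.0),
                         0.0, 1.0), 0.0)
    t = np.where(e > 1e-14,
                 np.clip((b * s + f) / np.where(e > 1e-14, e, 1.0), 0.0, 1.0),
                 0.0)
    # re-clamp s against the clamped t
    if a > 1e-14:
        s = np.clip((b * t - c) / a, 0.0, 1.0)
    cp1 = p0[None, :] + s[:, None] * d1[None, :]
    cp2 = q0 + t[:, None] * d2
    return np.linalg.norm(cp1 - cp2, axis=1)


def _collides(cand: Primitive, p0: np.ndarray, p1: np.ndarray,
              radii: np.ndarray, skip: int | None = None) -> bool:
    if p0.shape[0] == 0:
        return False
    a0, a1 = cand.endpoints
    d = segment_distance(a0, a1, p0, p1)
    limit = radii + cand.radius - _OVERLAP_SLACK
    if skip is not None:
        d = np.delete(d, skip)
        limit = np.delete(limit, skip)
    return bool(np.any(d < limit))


def _anchor_inside(prim: Primitive, envelope: CrownEnvelope,
                   tol: float = _CONTAIN_TOL) -> bool:
    x, y, z = prim.center
    if z < -tol or z > envelope.H + tol:
        return False
    z_cl = min(max(z, 0.0), envelope.H)
    rho = envelope.H * math.tan(envelope.alpha) * math.sqrt(
        max(0.0, float(envelope.sq_radius_norm(z_cl / envelope.H))))
    return math.hypot(x, y) <= rho + tol


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _split_species(specs) -> tuple[ScattererSpec, ScattererSpec]:
    support = leaf = None
    for s in specs:
        if s.shape == "cylinder" and abs(s.axis[2]) > 0.9:
            support = s
        else:
            leaf = s
    if support is None or leaf is None:
        raise ValueError("need one vertical cylinder species (stalk/branch) "
                         "and one leaf species")
    return support, leaf


def place_components(envelope: CrownEnvelope, plans: list[LayerPlan],
                     specs, seed: int,
                     max_attempts: int = 10_000) -> Canopy3D:
    """Place stalks/branches and surface-attached leaves, collision-free.

    Stalks are vertical, uniformly distributed over the admissible
    cross-section of their layer; each leaf is horizontal and attached at a
    uniformly random height and azimuth to the surface of a uniformly chosen
    stalk of the same layer. Reproducible from the seed; raises naming the
    layer if a primitive cannot be placed within ``max_attempts``.
    """
    rng = np.random.default_rng(seed)
    support, leaf = _split_species(specs)
    H, alpha = envelope.H, envelope.alpha
    tanr = math.tan(alpha)

    def rho_at(z: float) -> float:
        z = min(max(z, 0.0), H)
        return H * tanr * math.sqrt(
            max(0.0, float(envelope.sq_radius_norm(z / H))))

    prims: list[Primitive] = []
    p0 = np.zeros((0, 3))
    p1 = np.zeros((0, 3))
    radii = np.zeros(0)
    attempts_total = 0
    layer_counts = []

    def push(prim: Primitive) -> None:
        nonlocal p0, p1, radii
        prims.append(prim)
        a0, a1 = prim.endpoints
        p0 = np.vstack([p0, a0])
        p1 = np.vstack([p1, a1])
        radii = np.append(radii, prim.radius)

    for plan in plans:
        layer_stalks = []
        length = support.thickness_or_length
        z_min = plan.z_lo
        z_max = min(plan.z_hi, H) - length
        for i_st in range(plan.count):
            placed = False
            for _ in range(max_attempts):
                attempts_total += 1
                z_base = z_min if z_max <= z_min else float(
                    rng.uniform(z_min, z_max))
                if z_base + length > H + 1e-9:
                    z_base = max(0.0, H - length)
                rho_lim = rho_at(z_base + length / 2.0)
                if rho_lim <= 0.0:
                    x = y = 0.0
                else:
                    # uniform over the admissible disc
                    rr = rho_lim * math.sqrt(float(rng.uniform()))
                    th = float(rng.uniform(0.0, 2.0 * math.pi))
                    x, y = rr * math.cos(th), rr * math.sin(th)
                cand = Primitive("cylinder", (x, y, z_base + length / 2.0),
                                 (0.0, 0.0, 1.0), support.radius, length)
                if not _anchor_inside(cand, envelope):
                    continue
                if _collides(cand, p0, p1, radii):
                    continue
                push(cand)
                layer_stalks.append(len(prims) - 1)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place stalk {i_st + 1}/{plan.count} in layer "
                    f"{plan.index} after {max_attempts} attempts")
        # leaves: one per stalk count, attached to a random stalk surface
        for i_lf in range(plan.count):
            placed = False
            for _ in range(max_attempts):
                attempts_total += 1
                parent_idx = layer_stalks[int(rng.integers(len(layer_stalks)))]
                parent = prims[parent_idx]
                pz0, pz1 = parent.endpoints
                z_att = float(rng.uniform(pz0[2], pz1[2]))
                beta = float(rng.uniform(0.0, 2.0 * math.pi))
                ca, sa = math.cos(beta), math.sin(beta)
                if leaf.shape == "disc":
                    # horizontal disc tangent to the stalk surface
                    dist = parent.radius + leaf.radius
                    center = (pz0[0] + dist * ca, pz0[1] + dist * sa, z_att)
                    cand = Primitive("disc", center, (0.0, 0.0, 1.0),
                                     leaf.radius, leaf.thickness_or_length)
                else:
                    # horizontal needle sticking out radially; in the capsule
                    # collision model tangency means the needle axis starts
                    # one radius sum away from the branch axis
                    half = leaf.thickness_or_length / 2.0
                    dist = parent.radius + leaf.radius + half
                    center = (pz0[0] + dist * ca, pz0[1] + dist * sa, z_att)
                    cand = Primitive("cylinder", center, (ca, sa, 0.0),
                                     leaf.radius, leaf.thickness_or_length)
                if not _anchor_inside(cand, envelope):
                    continue
                if _collides(cand, p0, p1, radii, skip=parent_idx):
                    continue
                # against the parent, allow tangency but not interpenetration
                a0, a1 = cand.endpoints
                d_par = float(segment_distance(a0, a1, p0[parent_idx],
                                               p1[parent_idx])[0])
                if d_par < parent.radius + cand.radius - 1e-6:
                    continue
                push(cand)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place leaf {i_lf + 1}/{plan.count} in layer "
                    f"{plan.index} after {max_attempts} attempts")
        layer_counts.append(plan.count)

    return Canopy3D(envelope=envelope, primitives=prims, seed=seed,
                    layer_counts=layer_counts, attempts=attempts_total)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    containment_violations: list[int]
    overlap_pairs: list[tuple[int, int]]
    count_mismatches: list[tuple[int, int, int]]   # (layer, expected, found)

    @property
    def ok(self) -> bool:
        return not (self.containment_violations or self.overlap_pairs
                    or self.count_mismatches)


def validate_canopy(canopy: Canopy3D,
                    plans: list[LayerPlan] | None = None) -> ValidationReport:
    """Check containment, pairwise overlaps and per-layer counts.

    Overlaps are detected with the same strict segment-distance test used
    during placement, applied to every pair; attached leaves touching their
    parent are tangent, not overlapping.
    """
    env = canopy.envelope
    contain = [i for i, p in enumerate(canopy.primitives)
               if not _anchor_inside(p, env)]
    p0, p1, radii = _segment_arrays(canopy.primitives)
    overlaps = []
    for i in range(len(canopy.primitives) - 1):
        d = segment_distance(p0[i], p1[i], p0[i + 1:], p1[i + 1:])
        hits = np.nonzero(d < radii[i + 1:] + radii[i] - 1e-6)[0]
        overlaps.extend((i, i + 1 + int(j)) for j in hits)
    mismatches = []
    if plans is not None:
        supports = [p for p in canopy.primitives
                    if p.kind == "cylinder" and abs(p.axis[2]) > 0.9]
        for plan in plans:
            last = plan.index == len(plans) - 1
            hi = plan.z_hi + 1e-9 if last else plan.z_hi - 1e-9
            found = sum(1 for p in supports
                        if plan.z_lo - 1e-9 <= p.endpoints[0][2] < hi)
            if found != plan.count:
                mismatches.append((plan.index, plan.count, found))
    return ValidationReport(contain, overlaps, mismatches)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _tessellate(prim: Primitive, segments: int):
    """Closed triangle mesh (vertices, faces) of a capped cylinder/disc."""
    c = np.asarray(prim.center)
    a = np.asarray(prim.axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, a)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    h = 0.5 * prim.length
    ang = 2.0 * math.pi * np.arange(segments) / segments
    rim = prim.radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
    bot = c - h * a + rim
    top = c + h * a + rim
    verts = np.vstack([bot, top, c - h * a, c + h * a])
    ib, it = 2 * segments, 2 * segments + 1
    faces = []
    for i in range(segments):
        j = (i + 1) % segments
        faces.append((i, j, segments + i))            # side lower
        faces.append((j, segments + j, segments + i))  # side upper
        faces.append((ib, j, i))                       # bottom cap
        faces.append((it, segments + i, segments + j))  # top cap
    return verts, np.array(faces, dtype=int)


def export_geometry(canopy: Canopy3D, path: str, fmt: str = "stl",
                    segments: int = 32) -> None:
    """Write the canopy as an ASCII STL or OBJ triangle mesh."""
    fmt = fmt.lower()
    if fmt not in ("stl", "obj"):
        raise ValueError(f"unsupported format {fmt!r}")
    meshes = [_tessellate(p, segments) for p in canopy.primitives]
    with open(path, "w") as fh:
        if fmt == "stl":
            fh.write("solid canopy\n")
            for verts, faces in meshes:
                for f in faces:
                    v0, v1, v2 = verts[f[0]], verts[f[1]], verts[f[2]]
                    nrm = np.cross(v1 - v0, v2 - v0)
                    ln = np.linalg.norm(nrm)
                    nrm = nrm / ln if ln > 0 else nrm
                    fh.write(f"  facet normal {nrm[0]:.6e} {nrm[1]:.6e} "
                             f"{nrm[2]:.6e}\n    outer loop\n")
                    for v in (v0, v1, v2):
                        fh.write(f"      vertex {v[0]:.6e} {v[1]:.6e} "
                                 f"{v[2]:.6e}\n")
                    fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid canopy\n")
        else:
            offset = 1
            for verts, faces in meshes:
                for v in verts:
                    fh.write(f"v {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
                for f in faces:
                    fh.write(f"f {f[0] + offset} {f[1] + offset} "
                             f"{f[2] + offset}\n")
                offset += len(verts)


_MANIFEST_COLUMNS = ["kind", "x_cm", "y_cm", "z_cm", "axis_x", "axis_y",
                     "axis_z", "radius_cm", "length_cm"]


def write_manifest(canopy: Canopy3D, path: str) -> None:
    """CSV manifest, one primitive per row with pose and dimensions."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for p in canopy.primitives:
            writer.writerow([p.kind, *(repr(float(v)) for v in p.center),
                             *(repr(float(v)) for v in p.axis),
                             repr(float(p.radius)), repr(float(p.length))])


def read_manifest(path: str) -> list[Primitive]:
    """Re-read a CSV manifest into primitives (exact round trip)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(Primitive(
                kind=row["kind"],
                center=(float(row["x_cm"]), float(row["y_cm"]),
                        float(row["z_cm"])),
                axis=(float(row["axis_x"]), float(row["axis_y"]),
                      float(row["axis_z"])),
                radius=float(row["radius_cm"]),
                length=float(row["length_cm"]),
            ))
    return out
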