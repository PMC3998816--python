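"""2D sample cross-sections as prioritized material regions.

Samples are translation-invariant in y (the imaging slice reduction), so a
phantom is a set of 2D regions in the (x, z) plane: circles (cylinder
cross-sections), convex intersections of half-planes (slabs, wedges) and
clusters of many identical circles (sub-pixel scatterer ensembles).  Every
point maps to exactly one material: the highest-priority containing region,
else the background.  Ray-boundary intersections are exact (quadratic /
linear closed forms), which keeps the Monte Carlo transport free of any
geometric discretization error.

Clusters exist for performance: the dark-field phantom contains ~1200
micrometre-scale cylinders, and grouping them under a bounding circle lets
the vectorized ray tracer skip the members for rays that never enter the
bounding circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .materials import MaterialSpec, get_material

__all__ = [
    "ESCAPED",
    "CircleRegion",
    "ConvexRegion",
    "CircleCluster",
    "BoundaryCrossing",
    "Phantom",
    "GeometryEngine",
    "annulus",
    "build_hollow_cylinder_phantom",
    "build_ethanol_phantom",
    "build_darkfield_phantom",
    "build_cylinder_phantom",
    "build_slab_phantom",
    "build_wedge_phantom",
    "phantom_from_dict",
    "phantom_to_dict",
]

#: Minimum accepted ray-parameter for an intersection (m); guards against
#: re-hitting the surface a photon was just placed on.
T_EPS = 1e-10


class _Escaped:
    """Sentinel material for points outside the phantom bounding box."""

    name = "escaped"

    def __repr__(self):  # pragma: no cover
        return "ESCAPED"


ESCAPED = _Escaped()


@dataclass(frozen=True)
class CircleRegion:
    center: tuple  # (x, z) in m
    radius: float  # m
    material: MaterialSpec
    priority: int = 1

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ConvexRegion:
    """Intersection of half-planes n.p <= c; each plane is (nx, nz, c)."""

    planes: tuple
    material: MaterialSpec
    priority: int = 1

    def __post_init__(self):
        for nx, nz, _ in self.planes:
            n = math.hypot(nx, nz)
            if abs(n - 1.0) > 1e-9:
                raise ValueError("half-plane normals must be unit vectors")


@dataclass(frozen=True)
class CircleCluster:
    """Many same-size circles of one material under a bounding circle."""

    centers: np.ndarray  # (M, 2)
    radius: float
    material: MaterialSpec
    priority: int
    bound: tuple  # (cx, cz, rb)


@dataclass(frozen=True)
class BoundaryCrossing:
    distance: float
    normal: tuple  # unit (nx, nz), oriented from the 'from' into the 'to' side
    materials: tuple  # (from, to); 'to' may be ESCAPED

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("crossing distance must be positive")


def annulus(center, r_inner, r_outer, material, inner_material,
            priority=1) -> list:
    """An annulus as two nested circle regions (inner wins by priority)."""
    if not 0 < r_inner < r_outer:
        raise ValueError(f"need 0 < r_inner < r_outer, got {r_inner}, {r_outer}")
    return [
        CircleRegion(center, r_outer, material, priority),
        CircleRegion(center, r_inner, inner_material, priority + 1),
    ]


@dataclass(frozen=True)
class Phantom:
    regions: tuple  # CircleRegion | ConvexRegion
    background: MaterialSpec
    bbox: tuple  # (xmin, xmax, zmin, zmax) in m
    clusters: tuple = ()
    seed: int | None = None  # RNG seed used to build stochastic geometry

    def locate(self, point):
        """Material at a 2D point (x, z); ESCAPED outside the bounding box."""
        return GeometryEngine(self).locate_one(point)

    def next_boundary(self, origin, direction) -> BoundaryCrossing:
        return GeometryEngine(self).next_boundary_one(origin, direction)

    def rotated(self, angle_rad: float) -> "Phantom":
        """Phantom rotated by ``angle_rad`` about the origin in (x, z)."""
        c, s = math.cos(angle_rad), math.sin(angle_rad)

        def rot(p):
            return (c * p[0] - s * p[1], s * p[0] + c * p[1])

        regions = []
        for r in self.regions:
            if isinstance(r, CircleRegion):
                regions.append(replace(r, center=rot(r.center)))
            else:
                planes = tuple((c * nx - s * nz, s * nx + c * nz, cc)
                               for nx, nz, cc in r.planes)
                regions.append(replace(r, planes=planes))
        clusters = []
        for cl in self.clusters:
            rotm = np.array([[c, -s], [s, c]])
            clusters.append(replace(
                cl,
                centers=cl.centers @ rotm.T,
                bound=(*rot(cl.bound[:2]), cl.bound[2]),
            ))
        return replace(self, regions=tuple(regions), clusters=tuple(clusters))


class _CompiledCluster:
    """Uniform-grid spatial index over a cluster's member circles.

    Members are registered in every square cell their bounding box
    overlaps; rays inside the cluster bound only test the members of their
    current cell and treat cell walls (and the bound circle itself) as
    pseudo boundaries with no material change.
    """

    def __init__(self, cl: CircleCluster):
        self.cl = cl
        bx, bz, rb = cl.bound
        r = cl.radius
        self.g = max(rb / 8.0, 3.0 * r)
        self.n = max(int(math.ceil(2.0 * rb / self.g)), 1)
        self.x0 = bx - rb
        self.z0 = bz - rb
        cells = [[] for _ in range(self.n * self.n)]
        for m, (cx, cz) in enumerate(np.asarray(cl.centers)):
            i0 = max(int((cx - r - self.x0) // self.g), 0)
            i1 = min(int((cx + r - self.x0) // self.g), self.n - 1)
            j0 = max(int((cz - r - self.z0) // self.g), 0)
            j1 = min(int((cz + r - self.z0) // self.g), self.n - 1)
            for i in range(i0, i1 + 1):
                for j in range(j0, j1 + 1):
                    cells[i * self.n + j].append(m)
        maxm = max((len(c) for c in cells), default=0) or 1
        nmem = len(cl.centers)
        self.members = np.full((self.n * self.n, maxm), nmem, dtype=int)
        for c, lst in enumerate(cells):
            self.members[c, :len(lst)] = lst
        # sentinel row: a far-away circle that never matches
        self.centers_ext = np.vstack([np.asarray(cl.centers),
                                      [[1e30, 1e30]]])

    def cell_of(self, x, z):
        ix = np.clip(((x - self.x0) // self.g).astype(int), 0, self.n - 1)
        iz = np.clip(((z - self.z0) // self.g).astype(int), 0, self.n - 1)
        return ix, iz

    def member_circles(self, x, z):
        """(centers (n_pts, maxm, 2), radius) of the cells holding points."""
        ix, iz = self.cell_of(x, z)
        mem = self.members[ix * self.n + iz]
        return self.centers_ext[mem], self.cl.radius


class GeometryEngine:
    """Compiled, vectorized point-location and ray-tracing for a phantom.

    Works on arrays of positions/directions; used by the transport loop and
    by the projection-approximation line integrator.  Cluster regions use a
    uniform-grid index so rays only test nearby member circles.
    """

    def __init__(self, phantom: Phantom):
        self.phantom = phantom
        # material table: 0 = background, then one id per region/cluster
        self.materials = [phantom.background]
        circ, circ_mat, circ_prio = [], [], []
        self.convex = []  # (planes array, matid, priority)
        for r in phantom.regions:
            self.materials.append(r.material)
            mid = len(self.materials) - 1
            if isinstance(r, CircleRegion):
                circ.append((*r.center, r.radius))
                circ_mat.append(mid)
                circ_prio.append(r.priority)
            else:
                self.convex.append((np.asarray(r.planes, float), mid, r.priority))
        self.circ = np.asarray(circ, float).reshape(-1, 3)
        self.circ_mat = np.asarray(circ_mat, int)
        self.circ_prio = np.asarray(circ_prio, int)
        self.clusters = []
        for cl in phantom.clusters:
            self.materials.append(cl.material)
            mid = len(self.materials) - 1
            self.clusters.append((cl, mid, _CompiledCluster(cl)))
        self.bbox = phantom.bbox

    # -- point location ----------------------------------------------------

    def locate_ids(self, x, z):
        """Material-table index per point; -1 where outside the bbox."""
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        out = np.zeros(x.shape, int)
        prio = np.full(x.shape, -(10**9))
        for i in range(len(self.circ)):
            cx, cz, r = self.circ[i]
            inside = (x - cx) ** 2 + (z - cz) ** 2 <= r * r
            take = inside & (self.circ_prio[i] > prio)
            out[take] = self.circ_mat[i]
            prio[take] = self.circ_prio[i]
        for planes, mid, p in self.convex:
            inside = np.ones(x.shape, bool)
            for nx, nz, c in planes:
                inside &= nx * x + nz * z <= c
            take = inside & (p > prio)
            out[take] = mid
            prio[take] = p
        for cl, mid, idx_c in self.clusters:
            bx, bz, rb = cl.bound
            cand = (x - bx) ** 2 + (z - bz) ** 2 <= rb * rb
            cand &= cl.priority > prio
            if np.any(cand):
                idx = np.nonzero(cand)
                centers, r = idx_c.member_circles(x[idx], z[idx])
                d2 = ((x[idx][:, None] - centers[..., 0]) ** 2
                      + (z[idx][:, None] - centers[..., 1]) ** 2)
                hit = np.any(d2 <= r * r, axis=1)
                sel = tuple(a[hit] for a in idx)
                out[sel] = mid
                prio[sel] = cl.priority
        xmin, xmax, zmin, zmax = self.bbox
        out[(x < xmin) | (x > xmax) | (z < zmin) | (z > zmax)] = -1
        return out

    def material_of(self, mid: int):
        return ESCAPED if mid < 0 else self.materials[mid]

    def locate_one(self, point):
        mid = self.locate_ids(np.array([point[0]]), np.array([point[1]]))[0]
        return self.material_of(int(mid))

    # -- ray tracing -------------------------------------------------------

    @staticmethod
    def _circle_first_hit(px, pz, dx, dz, cx, cz, r):
        """Smallest ray parameter > T_EPS hitting the circle, else inf.

        The ray parameter is 3D arc length; (dx, dz) is the transverse
        projection of a unit 3D direction and may have norm < 1.
        """
        ox = px - cx
        oz = pz - cz
        a = dx * dx + dz * dz
        b = dx * ox + dz * oz
        c0 = ox * ox + oz * oz - r * r
        disc = b * b - a * c0
        ok = (disc > 0.0) & (a > 0.0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / a
            t2 = (-b + sq) / a
        t1 = np.where(t1 > T_EPS, t1, np.inf)
        t2 = np.where(t2 > T_EPS, t2, np.inf)
        return np.where(ok, np.minimum(t1, t2), np.inf)

    def next_boundary_arrays(self, px, pz, dx, dz):
        """First boundary along each ray.

        Returns ``(t, nx, nz)``: distance (m; exit of the bounding box if no
        region boundary is closer) and the unit surface normal there (the
        bbox face normal for bbox exits).
        """
        px, pz, dx, dz = (np.asarray(a, float) for a in (px, pz, dx, dz))
        n = px.shape[0]
        best = np.full(n, np.inf)
        nx = np.zeros(n)
        nz = np.zeros(n)

        def consider_circle(t, cx, cz, r):
            nonlocal best, nx, nz
            take = t < best
            if np.any(take):
                best = np.where(take, t, best)
                tf = np.where(np.isfinite(t), t, 0.0)
                hx = px + tf * dx - cx
                hz = pz + tf * dz - cz
                nx = np.where(take, hx / r, nx)
                nz = np.where(take, hz / r, nz)

        for i in range(len(self.circ)):
            cx, cz, r = self.circ[i]
            consider_circle(self._circle_first_hit(px, pz, dx, dz, cx, cz, r),
                            cx, cz, r)

        for planes, _, _ in self.convex:
            for pnx, pnz, c in planes:
                denom = pnx * dx + pnz * dz
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = (c - (pnx * px + pnz * pz)) / denom
                t = np.where((np.abs(denom) > 1e-300) & (t > T_EPS), t, np.inf)
                # the plane is a region boundary only where the other planes
                # are satisfied at the hit point
                tf = np.where(np.isfinite(t), t, 0.0)
                hx = px + tf * dx
                hz = pz + tf * dz
                valid = np.isfinite(t)
                for qnx, qnz, qc in planes:
                    if (qnx, qnz, qc) == (pnx, pnz, c):
                        continue
                    valid &= qnx * hx + qnz * hz <= qc + 1e-12
                t = np.where(valid, t, np.inf)
                take = t < best
                if np.any(take):
                    best = np.where(take, t, best)
                    nx = np.where(take, pnx, nx)
                    nz = np.where(take, pnz, nz)

        for cl, _, idxc in self.clusters:
            bx, bz, rb = cl.bound
            ox = px - bx
            oz = pz - bz
            a = dx * dx + dz * dz
            b = dx * ox + dz * oz
            c0 = ox * ox + oz * oz - rb * rb
            inside = c0 <= 0
            disc = b * b - a * c0
            sq = np.sqrt(np.maximum(disc, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_ent = np.where(inside, 0.0, (-b - sq) / a)
                t_exit = (-b + sq) / a
            hits = (disc > 0) & (a > 0) & (t_exit > T_EPS)
            if not np.any(hits & (t_ent < best)):
                continue
            # rays outside the bound: treat the bound circle as a pseudo
            # boundary (no material change) -- keeps the member test to the
            # rays currently inside the bound
            outer = hits & ~inside & (t_ent > T_EPS) & (t_ent < best)
            if np.any(outer):
                t = np.where(outer, t_ent, np.inf)
                take = t < best
                best = np.where(take, t, best)
                tf = np.where(np.isfinite(t), t, 0.0)
                hx = px + tf * dx - bx
                hz = pz + tf * dz - bz
                nx = np.where(take, hx / rb, nx)
                nz = np.where(take, hz / rb, nz)
            active = hits & inside
            if not np.any(active):
                continue
            idx = np.nonzero(active)[0]
            sx, sz, sdx, sdz = px[idx], pz[idx], dx[idx], dz[idx]
            sa = sdx * sdx + sdz * sdz
            # cell-wall exit (pseudo boundary): rays only test the members
            # of their current cell, so they may not step past its walls
            ix, iz = idxc.cell_of(sx, sz)
            with np.errstate(divide="ignore", invalid="ignore"):
                twx = np.where(
                    sdx > 0, (idxc.x0 + (ix + 1) * idxc.g - sx) / sdx,
                    np.where(sdx < 0, (idxc.x0 + ix * idxc.g - sx) / sdx,
                             np.inf))
                twz = np.where(
                    sdz > 0, (idxc.z0 + (iz + 1) * idxc.g - sz) / sdz,
                    np.where(sdz < 0, (idxc.z0 + iz * idxc.g - sz) / sdz,
                             np.inf))
            t_wall = np.maximum(np.minimum(twx, twz), T_EPS)
            wall_nx = np.where(twx < twz, np.sign(sdx), 0.0)
            wall_nz = np.where(twx < twz, 0.0, np.sign(sdz))
            t_cap = np.minimum(t_wall, t_exit[idx])
            centers, r = idxc.member_circles(sx, sz)
            ocx = sx[:, None] - centers[..., 0]
            ocz = sz[:, None] - centers[..., 1]
            bb = sdx[:, None] * ocx + sdz[:, None] * ocz
            cc = ocx**2 + ocz**2 - r * r
            dd = bb * bb - sa[:, None] * cc
            ok = dd > 0
            sq = np.sqrt(np.where(ok, dd, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (-bb - sq) / sa[:, None]
                t2 = (-bb + sq) / sa[:, None]
            t1 = np.where(ok & (t1 > T_EPS), t1, np.inf)
            t2 = np.where(ok & (t2 > T_EPS), t2, np.inf)
            tm = np.minimum(t1, t2)
            # a member hit only counts within the current cell (+ tol)
            tm = np.where(tm <= t_cap[:, None] + 1e-12, tm, np.inf)
            j = np.argmin(tm, axis=1)
            tbest = tm[np.arange(len(idx)), j]
            # fall back to the nearest pseudo boundary (cell wall or bound
            # exit, whichever is closer)
            use_wall = t_wall <= t_exit[idx]
            pseudo_t = np.where(use_wall, t_wall, t_exit[idx])
            hit_member = tbest < pseudo_t
            t_evt = np.where(hit_member, tbest, pseudo_t)
            take = t_evt < best[idx]
            if np.any(take):
                sel = idx[take]
                mhit = hit_member[take]
                best[sel] = t_evt[take]
                # normals: member circle / cell wall / bound circle
                jj = j[take]
                hx = px[sel] + best[sel] * dx[sel]
                hz = pz[sel] + best[sel] * dz[sel]
                mem_nx = (hx - centers[take, jj, 0]) / r
                mem_nz = (hz - centers[take, jj, 1]) / r
                bnd_nx = (hx - bx) / rb
                bnd_nz = (hz - bz) / rb
                nnx = np.where(mhit, mem_nx,
                               np.where(use_wall[take], wall_nx[take], bnd_nx))
                nnz = np.where(mhit, mem_nz,
                               np.where(use_wall[take], wall_nz[take], bnd_nz))
                nx[sel] = nnx
                nz[sel] = nnz

        # bounding box exit
        xmin, xmax, zmin, zmax = self.bbox
        with np.errstate(divide="ignore"):
            tx = np.where(dx > 0, (xmax - px) / dx,
                          np.where(dx < 0, (xmin - px) / dx, np.inf))
            tz = np.where(dz > 0, (zmax - pz) / dz,
                          np.where(dz < 0, (zmin - pz) / dz, np.inf))
        tbb = np.maximum(np.minimum(tx, tz), T_EPS)
        take = tbb < best
        bnx = np.where(tx < tz, np.sign(dx), 0.0)
        bnz = np.where(tx < tz, 0.0, np.sign(dz))
        best = np.where(take, tbb, best)
        nx = np.where(take, bnx, nx)
        nz = np.where(take, bnz, nz)
        return best, nx, nz

    def next_boundary_one(self, origin, direction) -> BoundaryCrossing:
        d = np.asarray(direction, float)
        if abs(np.hypot(d[0], d[1]) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector in (x, z)")
        t, nx, nz = self.next_boundary_arrays(
            *(np.array([v], float) for v in (origin[0], origin[1], d[0], d[1])))
        t = float(t[0])
        hit = (origin[0] + t * d[0], origin[1] + t * d[1])
        frm = self.material_of(int(self.locate_ids(
            np.array([origin[0]]), np.array([origin[1]]))[0]))
        eps = max(1e-10, 1e-12 * t)
        to = self.material_of(int(self.locate_ids(
            np.array([hit[0] + eps * d[0]]), np.array([hit[1] + eps * d[1]]))[0]))
        # orient the normal from the 'from' side into the 'to' side
        n = (float(nx[0]), float(nz[0]))
        if n[0] * d[0] + n[1] * d[1] < 0:
            n = (-n[0], -n[1])
        return BoundaryCrossing(t, n, (frm, to))


# ---------------------------------------------------------------------------
# Built-in phantoms
# ---------------------------------------------------------------------------

def build_hollow_cylinder_phantom(outer_radius=5.5e-3, inner_radius=4.5e-3,
                                  material=None, surround=None) -> Phantom:
    """Hollow polypropylene cylinder (wall 4.5-5.5 mm radius) in air."""
    material = material or get_material("polypropylene")
    surround = surround or get_material("air")
    regions = annulus((0.0, 0.0), inner_radius, outer_radius, material,
                      surround)
    half = 1.4 * outer_radius
    return Phantom(tuple(regions), surround, (-half, half, -half, half))


def build_ethanol_phantom(host_radius=3.0e-3, hole_radius=0.8e-3,
                          ring_radius=1.8e-3) -> Phantom:
    """Polystyrene cylinder with five liquid-filled holes, in water.

    Centre hole: water.  Ring holes counter-clockwise from 45 degrees:
    33%, 50%, 66%, 100% ethanol (mass fractions).  The host sits in a
    water background (the aquarium).  Hole layout dimensions are free
    parameters of the phantom, not physics inputs.
    """
    water = get_material("water")
    regions = [CircleRegion((0.0, 0.0), host_radius, get_material("polystyrene"), 1),
               CircleRegion((0.0, 0.0), hole_radius, water, 2)]
    names = ["ethanol33", "ethanol50", "ethanol66", "ethanol"]
    for k, nm in enumerate(names):
        ang = math.radians(45.0 + 90.0 * k)
        c = (ring_radius * math.cos(ang), ring_radius * math.sin(ang))
        regions.append(CircleRegion(c, hole_radius, get_material(nm), 2))
    half = 1.4 * host_radius
    return Phantom(tuple(regions), water, (-half, half, -half, half))


def _pack_discs(rng, n, area_radius, disc_radius, max_tries=200000):
    """Rejection-sample n non-overlapping disc centres inside a circle."""
    centers = np.empty((n, 2))
    placed = 0
    tries = 0
    rmax = area_radius - disc_radius
    while placed < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} discs of r={disc_radius} in r={area_radius}")
        tries += 1
        r = rmax * np.sqrt(rng.random())
        th = 2 * np.pi * rng.random()
        p = np.array([r * np.cos(th), r * np.sin(th)])
        if placed and np.min(np.sum((centers[:placed] - p) ** 2, axis=1)) < (2 * disc_radius) ** 2:
            continue
        centers[placed] = p
        placed += 1
    return centers


def build_darkfield_phantom(seed: int, area_radius=0.075e-3,
                            cylinder_radius=1.0e-6,
                            counts=(381, 795)) -> Phantom:
    """Three PMMA structures probing sub-pixel scattering strength.

    A solid disc (radius 0.075 mm) plus two equal-size areas filled with
    randomly placed non-overlapping PMMA microcylinders (radius 1 um;
    381 and 795 of them).  Reproducible from ``seed``.
    """
    pmma = get_material("pmma")
    air = get_material("air")
    rng = np.random.default_rng(seed)
    ring = 0.10e-3
    ang = [math.radians(180.0), math.radians(60.0), math.radians(-60.0)]
    centers = [(ring * math.cos(a), ring * math.sin(a)) for a in ang]
    regions = (CircleRegion(centers[0], area_radius, pmma, 1),)
    clusters = []
    for c, n in zip(centers[1:], counts):
        local = _pack_discs(rng, n, area_radius, cylinder_radius)
        clusters.append(CircleCluster(
            centers=local + np.asarray(c),
            radius=cylinder_radius, material=pmma, priority=1,
            bound=(c[0], c[1], area_radius),
        ))
    half = 3.0 * (ring + area_radius)
    return Phantom(regions, air, (-half, half, -half, half),
                   clusters=tuple(clusters), seed=seed)


def build_cylinder_phantom(material=None, radius=0.75e-3, surround=None,
                           margin_factor=1.5) -> Phantom:
    """A single solid cylinder (default water) in air."""
    material = material or get_material("water")
    surround = surround or get_material("air")
    half = margin_factor * radius
    return Phantom((CircleRegion((0.0, 0.0), radius, material, 1),),
                   surround, (-half, half, -half, half))


def build_slab_phantom(material, thickness, z0=0.0, half_width=None,
                       surround=None) -> Phantom:
    """A slab of given thickness normal to the beam (z) axis."""
    surround = surround or get_material("vacuum")
    region = ConvexRegion(((0.0, -1.0, -z0), (0.0, 1.0, z0 + thickness)),
                          material, 1)
    hw = half_width if half_width is not None else max(10 * thickness, 1e-2)
    return Phantom((region,), surround,
                   (-hw, hw, z0 - 5 * thickness - 1e-3, z0 + 6 * thickness + 1e-3))


def build_wedge_phantom(material, slope, z0=0.0, extent=2e-3,
                        surround=None) -> Phantom:
    """A wedge with thickness t(x) = slope * x for x > 0, entrance at z0."""
    surround = surround or get_material("vacuum")
    nrm = math.hypot(slope, 1.0)
    region = ConvexRegion(
        ((0.0, -1.0, -z0),                      # z >= z0
         (-slope / nrm, 1.0 / nrm, z0 / nrm),   # z - z0 <= slope * x
         (1.0, 0.0, extent)),                   # x <= extent
        material, 1)
    zmax = z0 + slope * extent
    return Phantom((region,), surround,
                   (-extent, 1.5 * extent, z0 - 2e-3, zmax + 2e-3))


# ---------------------------------------------------------------------------
# Structured-text (de)serialization
# ---------------------------------------------------------------------------

_BUILDERS = {
    "hollow_cylinder": build_hollow_cylinder_phantom,
    "ethanol": build_ethanol_phantom,
    "darkfield": build_darkfield_phantom,
    "cylinder": build_cylinder_phantom,
}


def phantom_from_dict(d: dict) -> Phantom:
    """Build a phantom from a config mapping.

    Either ``{"builtin": "hollow_cylinder", "params": {...}}`` or an explicit
    primitive list ``{"background": name, "bbox": [...], "regions": [...]}``
    with primitives circle/annulus/halfplanes referencing materials by name.
    """
    if "builtin" in d:
        return _BUILDERS[d["builtin"]](**d.get("params", {}))
    regions = []
    for r in d["regions"]:
        mat = get_material(r["material"])
        prio = int(r.get("priority", 1))
        kind = r["type"]
        if kind == "circle":
            regions.append(CircleRegion(tuple(r["center"]), float(r["radius"]),
                                        mat, prio))
        elif kind == "annulus":
            regions.extend(annulus(tuple(r["center"]), float(r["r_inner"]),
                                   float(r["r_outer"]), mat,
                                   get_material(r["inner_material"]), prio))
        elif kind == "halfplanes":
            regions.append(ConvexRegion(tuple(tuple(p) for p in r["planes"]),
                                        mat, prio))
        else:
            raise ValueError(f"unknown primitive type {kind!r}")
    return Phantom(tuple(regions), get_material(d["background"]),
                   tuple(d["bbox"]), seed=d.get("seed"))


def phantom_to_dict(ph: Phantom) -> dict:
    regions = []
    for r in ph.regions:
        if isinstance(r, CircleRegion):
            regions.append({"type": "circle", "center": list(r.center),
                            "radius": r.radius, "material": r.material.name,
                            "priority": r.priority})
        else:
            regions.append({"type": "halfplanes",
                            "planes": [list(p) for p in r.planes],
                            "material": r.material.name,
                            "priority": r.priority})
    if ph.clusters:
        raise ValueError("cluster phantoms serialize via their builder + seed")
    return {"background": ph.background.name, "bbox": list(ph.bbox),
            "regions": regions, "seed": ph.seed}
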