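"""Triangulated-mesh compartments.

A compartment is a closed, manifold triangle mesh (every edge shared by
exactly two triangles, consistent counterclockwise winding seen from
outside).  The mesh is kept in a shared-vertex structure augmented with
per-triangle edge and neighbor arrays for surface navigation, and a
voxel grid over its bounding box for ray queries.

Geometric queries implemented here:

- barycentric point-in-triangle tests,
- closest point / distance from a point to a triangle (region
  classification over interior, edges and vertices),
- ray tracing with mirror reflection for volume molecules (voxel
  traversal to find candidate triangles, Moller-Trumbore intersection),
- surface ray marching for surface-bound molecules: a displacement in
  the current triangle plane is advanced to the first crossed edge and
  the residual is rotated about that edge into the neighbor triangle's
  plane, which is equivalent to unfolding the triangle fan into a common
  tangent plane; the path is a geodesic and its length is conserved.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CompartmentMesh",
    "MeshValidationError",
    "build_mesh",
    "load_obj",
    "save_obj",
    "point_in_triangle",
    "point_triangle_distance",
    "ray_trace_reflect",
    "surface_ray_march",
]

_EPS = 1e-9


class MeshValidationError(ValueError):
    def __init__(self, message, offending_edges=None):
        super().__init__(message)
        self.offending_edges = offending_edges or []


def _triangle_normal(v0, v1, v2):
    n = np.cross(v1 - v0, v2 - v0)
    nn = np.linalg.norm(n)
    if nn < 1e-14:
        raise ValueError("degenerate triangle (zero area)")
    return n / nn


class CompartmentMesh:
    """Closed triangulated manifold with adjacency and a voxel grid."""

    def __init__(self, vertices, triangles, face_groups=None, voxel_size=None):
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise MeshValidationError("triangle vertex index out of range")
        self.face_groups: dict[str, np.ndarray] = {
            k: np.asarray(v, dtype=np.int64) for k, v in (face_groups or {}).items()
        }
        self._build_adjacency()
        self._build_geometry()
        self._build_voxel_grid(voxel_size)

    # -- construction -------------------------------------------------
    def _build_adjacency(self):
        tris = self.triangles
        nf = len(tris)
        # edges per triangle, counterclockwise: (v0,v1), (v1,v2), (v2,v0)
        self.edges_per_triangle = np.stack(
            [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]], axis=1
        )  # (F, 3, 2)
        edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for f in range(nf):
            for k in range(3):
                a, b = self.edges_per_triangle[f, k]
                edge_map.setdefault((min(a, b), max(a, b)), []).append((f, k))
        bad = [e for e, users in edge_map.items() if len(users) != 2]
        if bad:
            raise MeshValidationError(
                f"mesh is not a closed manifold: {len(bad)} edge(s) not shared by "
                f"exactly two triangles (e.g. {bad[:5]})",
                offending_edges=bad,
            )
        self.neighbors = np.full((nf, 3), -1, dtype=np.int64)
        wind_bad = []
        for (a, b), ((f1, k1), (f2, k2)) in edge_map.items():
            self.neighbors[f1, k1] = f2
            self.neighbors[f2, k2] = f1
            # consistent winding: the shared edge runs in opposite directions
            if tuple(self.edges_per_triangle[f1, k1]) == tuple(
                self.edges_per_triangle[f2, k2]
            ):
                wind_bad.append((a, b))
        if wind_bad:
            raise MeshValidationError(
                f"inconsistent triangle winding across {len(wind_bad)} edge(s)",
                offending_edges=wind_bad,
            )
        self.n_edges = len(edge_map)

    def _build_geometry(self):
        v = self.vertices
        t = self.triangles
        self.tri_v0 = v[t[:, 0]]
        e1 = v[t[:, 1]] - self.tri_v0
        e2 = v[t[:, 2]] - self.tri_v0
        n = np.cross(e1, e2)
        areas2 = np.linalg.norm(n, axis=1)
        if np.any(areas2 < 1e-14):
            raise MeshValidationError("mesh contains degenerate (zero-area) triangles")
        self.normals = n / areas2[:, None]
        self.areas = 0.5 * areas2
        self.area = float(self.areas.sum())
        # signed volume (positive for outward CCW winding)
        self.volume = float(
            np.einsum("ij,ij->", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]]))
        ) / 6.0

    def _build_voxel_grid(self, voxel_size):
        lo = self.vertices.min(axis=0) - 1e-6
        hi = self.vertices.max(axis=0) + 1e-6
        ext = hi - lo
        if voxel_size is None:
            # aim at ~ F voxels total
            voxel_size = max(float((ext.prod() / max(len(self.triangles), 1)) ** (1 / 3)), 1e-6)
        nc = np.maximum(1, np.floor(ext / voxel_size).astype(np.int64))
        size = ext / nc
        self.voxel_origin = lo
        self.voxel_counts = nc
        self.voxel_size = size
        grid: dict[tuple[int, int, int], list[int]] = {}
        v, t = self.vertices, self.triangles
        for f in range(len(t)):
            tmin = v[t[f]].min(axis=0)
            tmax = v[t[f]].max(axis=0)
            c0 = np.clip(((tmin - lo) / size).astype(np.int64), 0, nc - 1)
            c1 = np.clip(((tmax - lo) / size).astype(np.int64), 0, nc - 1)
            for cx in range(c0[0], c1[0] + 1):
                for cy in range(c0[1], c1[1] + 1):
                    for cz in range(c0[2], c1[2] + 1):
                        grid.setdefault((cx, cy, cz), []).append(f)
        self.voxel_grid = {k: np.array(ids, dtype=np.int64) for k, ids in grid.items()}

    # -- queries ------------------------------------------------------
    def triangle_vertices(self, f: int) -> np.ndarray:
        return self.vertices[self.triangles[f]]

    def contains(self, point, rng=None) -> bool:
        """Inside/outside by ray-crossing parity (jittered direction on
        degenerate hits)."""
        point = np.asarray(point, dtype=float)
        direction = np.array([0.961524227, 0.199362733, 0.189237461])
        for attempt in range(8):
            hits = self._ray_all_hits(point, direction)
            ok = all(h[2] > 1e-7 for h in hits)  # no grazing/edge hits
            if ok:
                return len(hits) % 2 == 1
            # deterministic jitter
            direction = direction + np.array(
                [0.013 * (attempt + 1), -0.007 * (attempt + 2), 0.011]
            )
            direction /= np.linalg.norm(direction)
        return len(hits) % 2 == 1

    def _ray_all_hits(self, origin, direction):
        """All (t, face, min_bary) intersections of an infinite ray."""
        hits = []
        for f in range(len(self.triangles)):
            res = _ray_triangle(origin, direction, *self.triangle_vertices(f))
            if res is not None and res[0] > _EPS:
                hits.append((res[0], f, res[1]))
        return hits

    def first_hit(self, origin, direction, max_t):
        """Nearest triangle hit along origin + t*direction, t in (eps, max_t].

        Uses the voxel traversal to restrict candidate triangles; returns
        (t, face) or None.
        """
        best = None
        tested: set[int] = set()
        for cell, t_entry in _voxel_walk(
            origin, direction, max_t, self.voxel_origin, self.voxel_size, self.voxel_counts
        ):
            if best is not None and t_entry > best[0]:
                break  # every later voxel is entered beyond the found hit
            tris = self.voxel_grid.get(cell)
            if tris is None:
                continue
            for f in tris:
                if f in tested:
                    continue
                tested.add(f)
                res = _ray_triangle(origin, direction, *self.triangle_vertices(f))
                if res is None:
                    continue
                t = res[0]
                if _EPS < t <= max_t and (best is None or t < best[0]):
                    best = (t, int(f))
        return best


def build_mesh(vertices, triangles, face_groups=None) -> CompartmentMesh:
    """Validate and index a triangle mesh (closed manifold required)."""
    return CompartmentMesh(vertices, triangles, face_groups=face_groups)


def load_obj(path) -> CompartmentMesh:
    """Read a Wavefront OBJ file (triangles only; OBJ groups become
    face groups)."""
    import trimesh

    loaded = trimesh.load(str(path), file_type="obj", process=False, group_material=False)
    if isinstance(loaded, trimesh.Scene):
        groups = {}
        verts = []
        faces = []
        off = 0
        for name, geom in loaded.geometry.items():
            groups[name] = np.arange(len(geom.faces)) + sum(len(g) for g in groups.values())
            verts.append(np.asarray(geom.vertices))
            faces.append(np.asarray(geom.faces) + off)
            off += len(geom.vertices)
        return build_mesh(np.vstack(verts), np.vstack(faces), face_groups=groups)
    return build_mesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))


def save_obj(mesh: CompartmentMesh, path):
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(path), file_type="obj")


def validation_report(vertices, triangles) -> dict:
    """Mesh validation as a JSON-serializable report."""
    try:
        m = build_mesh(vertices, triangles)
    except MeshValidationError as err:
        return {
            "valid": False,
            "error": str(err),
            "offending_edges": [list(map(int, e)) for e in err.offending_edges],
        }
    return {
        "valid": True,
        "n_vertices": int(len(m.vertices)),
        "n_triangles": int(len(m.triangles)),
        "n_edges": int(m.n_edges),
        "euler_characteristic": int(len(m.vertices) - m.n_edges + len(m.triangles)),
        "area": m.area,
        "volume": m.volume,
    }


# -- point/triangle primitives ---------------------------------------


def point_in_triangle(p, v0, v1, v2, tol: float = 1e-9):
    """Barycentric containment test for a point in (the plane of) a
    triangle.

    Returns ``(inside, (u, v, w))`` with u+v+w = 1 (u belongs to v0);
    the closed convention accepts coordinates >= -tol.
    """
    p = np.asarray(p, dtype=float)
    e0 = np.asarray(v1, dtype=float) - v0
    e1 = np.asarray(v2, dtype=float) - v0
    d = p - v0
    d00 = e0 @ e0
    d01 = e0 @ e1
    d11 = e1 @ e1
    denom = d00 * d11 - d01 * d01
    if abs(denom) < 1e-16:
        raise ValueError("degenerate triangle")
    d20 = d @ e0
    d21 = d @ e1
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    return (u >= -tol) and (v >= -tol) and (w >= -tol), (u, v, w)


def point_triangle_distance(p, v0, v1, v2):
    """Distance and closest point from ``p`` to the closed triangle
    (region classification over face, edges and vertices)."""
    p = np.asarray(p, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    e0 = np.asarray(v1, dtype=float) - v0
    e1 = np.asarray(v2, dtype=float) - v0
    if np.linalg.norm(np.cross(e0, e1)) < 1e-14:
        raise ValueError("degenerate triangle")
    dv = v0 - p
    a = e0 @ e0
    b = e0 @ e1
    c = e1 @ e1
    d = e0 @ dv
    e = e1 @ dv
    det = a * c - b * b
    s = b * e - c * d
    t = b * d - a * e
    if s + t <= det:
        if s < 0:
            if t < 0:  # region 4
                if d < 0:
                    t = 0.0
                    s = min(max(-d / a, 0.0), 1.0)
                else:
                    s = 0.0
                    t = min(max(-e / c, 0.0), 1.0)
            else:  # region 3
                s = 0.0
                t = min(max(-e / c, 0.0), 1.0)
        elif t < 0:  # region 5
            t = 0.0
            s = min(max(-d / a, 0.0), 1.0)
        else:  # region 0 (interior)
            s /= det
            t /= det
    else:
        if s < 0:  # region 2
            tmp0 = b + d
            tmp1 = c + e
            if tmp1 > tmp0:
                numer = tmp1 - tmp0
                s = min(max(numer / (a - 2 * b + c), 0.0), 1.0)
                t = 1.0 - s
            else:
                s = 0.0
                t = min(max(-e / c, 0.0), 1.0)
        elif t < 0:  # region 6
            tmp0 = b + e
            tmp1 = a + d
            if tmp1 > tmp0:
                numer = tmp1 - tmp0
                t = min(max(numer / (a - 2 * b + c), 0.0), 1.0)
                s = 1.0 - t
            else:
                t = 0.0
                s = min(max(-d / a, 0.0), 1.0)
        else:  # region 1
            numer = (c + e) - (b + d)
            if numer <= 0:
                s = 0.0
            else:
                s = min(max(numer / (a - 2 * b + c), 0.0), 1.0)
            t = 1.0 - s
    closest = v0 + s * e0 + t * e1
    return float(np.linalg.norm(p - closest)), closest


def _ray_triangle(origin, direction, v0, v1, v2):
    """Moller-Trumbore; returns (t, min_barycentric) or None."""
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    a = e1 @ h
    if abs(a) < 1e-14:
        return None
    f = 1.0 / a
    s = origin - v0
    u = f * (s @ h)
    if u < -1e-12 or u > 1 + 1e-12:
        return None
    q = np.cross(s, e1)
    v = f * (direction @ q)
    if v < -1e-12 or u + v > 1 + 1e-12:
        return None
    t = f * (e2 @ q)
    if t <= 0:
        return None
    return float(t), float(min(u, v, 1.0 - u - v))


def _voxel_walk(origin, direction, max_t, grid_origin, size, counts):
    """Amanatides & Woo traversal: yields ``(cell, t_entry)`` along the
    ray until ``max_t``."""
    rel = (origin - grid_origin) / size
    cell = np.floor(rel).astype(np.int64)
    # clamp: rays may start outside the grid; advance to the grid box first
    lo = grid_origin
    hi = grid_origin + counts * size
    t = 0.0
    if np.any(origin < lo) or np.any(origin > hi):
        t_enter, t_exit = 0.0, max_t
        for d in range(3):
            if abs(direction[d]) < 1e-14:
                if origin[d] < lo[d] or origin[d] > hi[d]:
                    return
                continue
            ta = (lo[d] - origin[d]) / direction[d]
            tb = (hi[d] - origin[d]) / direction[d]
            t_enter = max(t_enter, min(ta, tb))
            t_exit = min(t_exit, max(ta, tb))
        if t_enter > t_exit or t_enter > max_t:
            return
        t = t_enter + 1e-12
        cell = np.floor((origin + t * direction - grid_origin) / size).astype(np.int64)
    cell = np.clip(cell, 0, counts - 1)
    step = np.where(direction > 0, 1, -1)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    for d in range(3):
        if abs(direction[d]) < 1e-14:
            t_max[d] = np.inf
            t_delta[d] = np.inf
        else:
            nxt = grid_origin[d] + (cell[d] + (1 if direction[d] > 0 else 0)) * size[d]
            t_max[d] = (nxt - origin[d]) / direction[d]
            t_delta[d] = size[d] / abs(direction[d])
    while True:
        yield (int(cell[0]), int(cell[1]), int(cell[2])), t
        d = int(np.argmin(t_max))
        if t_max[d] > max_t:
            return
        t = t_max[d]
        cell[d] += step[d]
        if cell[d] < 0 or cell[d] >= counts[d]:
            return
        t_max[d] += t_delta[d]


class StuckGeometryError(RuntimeError):
    pass


def ray_trace_reflect(origin, displacement, mesh: CompartmentMesh,
                      max_reflections: int = 50):
    """Translate ``origin`` by ``displacement``, mirror-reflecting the
    remaining path at every mesh triangle hit.

    Pure geometry: independent of the integration time step; the total
    path length equals |displacement|.  Returns ``(final_position,
    hits)`` with ``hits`` the list of (face, point) encountered.
    """
    pos = np.asarray(origin, dtype=float).copy()
    disp = np.asarray(displacement, dtype=float).copy()
    hits = []
    for _ in range(max_reflections):
        dist = np.linalg.norm(disp)
        if dist < 1e-14:
            return pos, hits
        direction = disp / dist
        hit = mesh.first_hit(pos, direction, dist)
        if hit is None:
            return pos + disp, hits
        t, face = hit
        point = pos + t * direction
        n = mesh.normals[face]
        remaining = direction * (dist - t)
        reflected = remaining - 2.0 * (remaining @ n) * n
        hits.append((int(face), point))
        # nudge off the surface to avoid re-hitting the same triangle
        pos = point + np.sign(-(direction @ n)) * n * 1e-9
        disp = reflected
    raise StuckGeometryError(
        f"more than {max_reflections} reflections; geometry trap at {pos}"
    )


def _rotation_about_axis(axis, angle):
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _axis_angle_quat(axis, angle):
    axis = axis / np.linalg.norm(axis)
    h = 0.5 * angle
    return np.concatenate([[np.cos(h)], np.sin(h) * axis])


def surface_ray_march(position, triangle, displacement, mesh: CompartmentMesh,
                      max_crossings: int = 500):
    """Advance a surface-bound molecule by an (in-plane) displacement.

    At each crossed edge the residual displacement is rotated about the
    shared edge into the neighboring triangle's plane; the traveled arc
    length equals |displacement|.  Returns ``(position, triangle,
    rotation_quaternion)`` where the quaternion is the composed rotation
    to apply to the molecule's orientation.

    ``displacement`` must lie in the plane of ``triangle`` (it is
    projected to guard against drift).
    """
    pos = np.asarray(position, dtype=float).copy()
    disp = np.asarray(displacement, dtype=float).copy()
    tri = int(triangle)
    quat = np.array([1.0, 0.0, 0.0, 0.0])
    for _ in range(max_crossings):
        n = mesh.normals[tri]
        # keep both point and direction in the triangle plane
        disp = disp - (disp @ n) * n
        v = mesh.triangle_vertices(tri)
        pos = pos - ((pos - v[0]) @ n) * n
        if np.linalg.norm(disp) < 1e-14:
            return pos, tri, quat
        target = pos + disp
        inside, _ = point_in_triangle(target, *v, tol=1e-12)
        if inside:
            return target, tri, quat
        # first crossed edge: solve pos + t*disp on the edge line
        best = None
        for k in range(3):
            a = v[k]
            b = v[(k + 1) % 3]
            e = b - a
            # outward edge normal in the triangle plane
            m = np.cross(e, n)
            denom = disp @ m
            if denom <= 1e-15:  # moving parallel or inward w.r.t. this edge
                continue
            t = ((a - pos) @ m) / denom
            if t < -1e-12:
                continue
            if best is None or t < best[0]:
                best = (max(t, 0.0), k)
        if best is None:
            # numerically on an edge pointing outward: nudge inward
            centroid = v.mean(axis=0)
            pos = pos + 1e-9 * (centroid - pos)
            continue
        t, k = best
        nbr = int(mesh.neighbors[tri, k])
        a, b = v[k], v[(k + 1) % 3]
        edge_dir = (b - a) / np.linalg.norm(b - a)
        pos = pos + t * disp
        disp = (1.0 - t) * disp
        n2 = mesh.normals[nbr]
        angle = np.arctan2(np.cross(n, n2) @ edge_dir, n @ n2)
        rot = _rotation_about_axis(edge_dir, angle)
        disp = rot @ disp
        dq = _axis_angle_quat(edge_dir, angle)
        quat = _quat_mul(dq, quat)
        tri = nbr
    raise StuckGeometryError("surface ray marching exceeded max edge crossings")


def _quat_mul(q1, q2):
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )
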