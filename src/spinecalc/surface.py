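"""Labeled triangle/quad surface mesh of the spine + dendrite + ER morphology.

Construction mirrors the parametric workflow the solver geometry is derived
from: each compartment boundary is a body of revolution built from a
piecewise-linear circle approximation (default 8 rim vertices), successively
extruded along its axis with quadrilateral barrel faces; the spine branch is
attached by remeshing a hole into the host barrel and stitching it to the
branch rim; spherical parts (spine head, ER head bulb) are rings of
latitude closed by an apex fan; planar holes at cylinder ends are closed by
triangle fans. Faces are labeled by the compartment subset they belong to.

The mesh is for export/visualization and geometric regression tests only;
the solver uses the closed-form control-volume grid, never this mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import SpineParams, validate_params, _spine_er_profile

PM_DENDRITE = "PM_dendrite"
PM_NECK = "PM_neck"
PM_HEAD = "PM_head"
SYNAPSE = "synapse"
ERM_DENDRITE = "ERM_dendrite"
ERM_SPINE = "ERM_spine"
CAP = "cap"


@dataclass
class SurfaceMesh:
    """Vertices (µm), mixed tri/quad faces, per-face subset label and
    compartment id (0 = outer/plasma membrane, 1 = ER)."""

    vertices: np.ndarray
    faces: list = field(default_factory=list)       # tuples of vertex indices
    labels: list = field(default_factory=list)      # subset label per face
    compartment: list = field(default_factory=list)  # 0 outer, 1 ER

    def face_area(self, f) -> float:
        v = self.vertices
        if len(f) == 3:
            return 0.5 * float(np.linalg.norm(
                np.cross(v[f[1]] - v[f[0]], v[f[2]] - v[f[0]])))
        a = 0.5 * np.linalg.norm(np.cross(v[f[1]] - v[f[0]], v[f[2]] - v[f[0]]))
        b = 0.5 * np.linalg.norm(np.cross(v[f[2]] - v[f[0]], v[f[3]] - v[f[0]]))
        return float(a + b)

    def subset_area(self, label: str) -> float:
        return sum(self.face_area(f)
                   for f, l in zip(self.faces, self.labels) if l == label)

    def edge_counts(self, comp: int) -> dict:
        """Edge -> number of incident faces, within one compartment."""
        counts: dict = {}
        for f, c in zip(self.faces, self.compartment):
            if c != comp:
                continue
            for a, b in zip(f, f[1:] + f[:1]):
                e = (a, b) if a < b else (b, a)
                counts[e] = counts.get(e, 0) + 1
        return counts

    def is_watertight(self, comp: int) -> bool:
        cnt = self.edge_counts(comp)
        return bool(cnt) and all(v == 2 for v in cnt.values())


class _Builder:
    def __init__(self):
        self.verts: list = []
        self.faces: list = []
        self.labels: list = []
        self.comp: list = []

    def add_vertex(self, xyz) -> int:
        self.verts.append(tuple(float(x) for x in xyz))
        return len(self.verts) - 1

    def add_face(self, idx, label, comp):
        self.faces.append(tuple(int(i) for i in idx))
        self.labels.append(label)
        self.comp.append(comp)

    def quad_strip(self, ring_a, ring_b, label, comp):
        n = len(ring_a)
        for k in range(n):
            self.add_face(
                (ring_a[k], ring_a[(k + 1) % n],
                 ring_b[(k + 1) % n], ring_b[k]), label, comp)

    def fan(self, center, ring, label, comp, flip=False):
        n = len(ring)
        for k in range(n):
            a, b = ring[k], ring[(k + 1) % n]
            tri = (center, b, a) if flip else (center, a, b)
            self.add_face(tri, label, comp)

    def zip_loops(self, outer, inner, angles_outer, angles_inner, label, comp):
        """Stitch two closed loops by marching in angular order."""
        no, ni = len(outer), len(inner)
        start_o = int(np.argmin(angles_outer))
        start_i = int(np.argmin(angles_inner))
        io, ii = 0, 0
        while io < no or ii < ni:
            o0 = outer[(start_o + io) % no]
            i0 = inner[(start_i + ii) % ni]
            ao_next = angles_outer[(start_o + io + 1) % no] + (
                2 * math.pi if io + 1 >= no else 0)
            ai_next = angles_inner[(start_i + ii + 1) % ni] + (
                2 * math.pi if ii + 1 >= ni else 0)
            if io < no and (ii >= ni or ao_next <= ai_next):
                o1 = outer[(start_o + io + 1) % no]
                self.add_face((o0, o1, i0), label, comp)
                io += 1
            else:
                i1 = inner[(start_i + ii + 1) % ni]
                self.add_face((o0, i1, i0), label, comp)
                ii += 1


def _circle_ring(builder, n, radius, axis, station, center2=(0.0, 0.0),
                 offset=0.0):
    """Ring of n vertices of a circle around `axis` ('z' or 'y')."""
    ring = []
    for k in range(n):
        th = offset + 2.0 * math.pi * k / n
        c, s = math.cos(th), math.sin(th)
        if axis == "z":
            ring.append(builder.add_vertex(
                (radius * c + center2[0], radius * s + center2[1], station)))
        else:  # spine axis y
            ring.append(builder.add_vertex(
                (radius * c + center2[0], station, radius * s + center2[1])))
    return ring


def _branch_hole(builder, n, r_cyl, r_hole, z_branch, stations, label, comp):
    """Barrel of a z-axis cylinder with a circular hole cut toward +y.

    Returns (rings, hole_loop, hole_angles): the hole loop is ordered for
    zipping against the branch rim (angles measured around the +y axis).
    """
    offset = math.pi / 2 - math.pi / n  # center one face on +y
    rings = [_circle_ring(builder, n, r_cyl, "z", z, offset=offset)
             for z in stations]
    # locate the strip containing the branch
    strip = None
    for i in range(len(stations) - 1):
        if stations[i] <= z_branch <= stations[i + 1]:
            strip = i
            break
    if strip is None:
        raise ValueError("branch position outside the cylinder")
    alpha = math.asin(min(0.999, r_hole / r_cyl)) * 1.25

    def delta(k):  # face-midpoint angle relative to +y, wrapped to (-pi, pi]
        return (2 * math.pi * k / n + math.pi) % (2 * math.pi) - math.pi

    removed = []
    for i, ring in enumerate(rings[:-1]):
        for k in range(n):
            in_hole = (i == strip
                       and abs(delta(k)) <= alpha + math.pi / n - 1e-12)
            if in_hole:
                removed.append(k)
            else:
                builder.add_face(
                    (ring[k], ring[(k + 1) % n],
                     rings[i + 1][(k + 1) % n], rings[i + 1][k]),
                    label, comp)
    # hole boundary loop, ordered by angle (the removed faces are
    # angle-contiguous around +y even when the index wraps)
    ks = sorted(removed, key=delta)
    i = strip
    bottom = [rings[i][ks[0]]] + [rings[i][(k + 1) % n] for k in ks]
    top = [rings[i + 1][ks[0]]] + [rings[i + 1][(k + 1) % n] for k in ks]
    loop = bottom + top[::-1]
    verts = np.array(builder.verts)
    pts = verts[loop]
    ang = np.arctan2(pts[:, 0], -(pts[:, 2] - z_branch))  # around +y axis
    return rings, loop, ang


def generate_surface_mesh(p: SpineParams, rim_vertices: int = 8) -> SurfaceMesh:
    """Construct the labeled, per-compartment watertight surface mesh."""
    validate_params(p)
    n = int(rim_vertices)
    if n < 3:
        raise ValueError("rim_vertices must be >= 3")
    b = _Builder()
    rh = p.head_radius_scaled
    yc = p.head_center_y
    zs = p.z_spine
    prof = _spine_er_profile(p)

    # ---------------- outer surface (PM + synapse + caps) -------------------
    w = min(1.6 * p.neck_radius, zs, p.dendrite_length - zs)
    target = max(p.dendrite_radius / 2.0, 1e-6)
    st_lo = np.linspace(0.0, zs - w, max(1, round((zs - w) / target)) + 1)
    st_hi = np.linspace(zs + w, p.dendrite_length,
                        max(1, round((p.dendrite_length - zs - w) / target)) + 1)
    stations = np.concatenate([st_lo, st_hi])
    rings, hole_loop, hole_ang = _branch_hole(
        b, n, p.dendrite_radius, p.neck_radius, zs, stations, PM_DENDRITE, 0)
    # dendrite end caps
    c0 = b.add_vertex((0.0, 0.0, 0.0))
    c1 = b.add_vertex((0.0, 0.0, p.dendrite_length))
    b.fan(c0, rings[0], CAP, 0, flip=True)
    b.fan(c1, rings[-1], CAP, 0)

    # neck rim on the dendrite surface, then extrusion to the head apex
    y0 = math.sqrt(max(p.dendrite_radius**2 - p.neck_radius**2, 0.0))
    ring_offset = math.pi / n
    neck_base = _circle_ring(b, n, p.neck_radius, "y", y0,
                             center2=(0.0, zs), offset=ring_offset)
    base_pts = np.array(b.verts)[neck_base]
    base_ang = np.arctan2(base_pts[:, 0], -(base_pts[:, 2] - zs))
    b.zip_loops(hole_loop, neck_base, hole_ang, base_ang, PM_DENDRITE, 0)

    y_nt, y_top = p.neck_top_y, p.spine_top_y
    syn_area = min(p.synapse_area, 2.0 * math.pi * rh * (y_top - y_nt))
    y_syn = y_top - syn_area / (2.0 * math.pi * rh)
    n_neck = max(2, round(p.neck_length / 0.2) + 1)
    n_head = max(6, 2 * n)
    y_ring = np.concatenate([
        np.linspace(y0, y_nt, n_neck),
        np.linspace(y_nt, y_top, n_head + 1)[1:-1],
    ])
    prev = neck_base
    prev_y = y0
    for y in y_ring[1:]:
        r = p.neck_radius if y <= y_nt else math.sqrt(
            max(rh * rh - (y - yc) ** 2, 0.0))
        ring = _circle_ring(b, n, r, "y", y, center2=(0.0, zs),
                            offset=ring_offset)
        mid = 0.5 * (prev_y + y)
        label = (PM_NECK if mid <= y_nt
                 else (SYNAPSE if mid >= y_syn else PM_HEAD))
        b.quad_strip(prev, ring, label, 0)
        prev, prev_y = ring, y
    apex = b.add_vertex((0.0, y_top, zs))
    apex_label = SYNAPSE if 0.5 * (prev_y + y_top) >= y_syn else PM_HEAD
    b.fan(apex, prev, apex_label, 0, flip=True)

    # ----------------------------- ER surface ------------------------------
    e0, e1 = p.dendrite_er_z0, p.dendrite_er_z1
    target_e = max(p.dendrite_er_radius, 0.05)
    if prof is None:
        st = np.linspace(e0, e1, max(1, round((e1 - e0) / target_e)) + 1)
        offset = math.pi / 2 - math.pi / n
        er_rings = [_circle_ring(b, n, p.dendrite_er_radius, "z", z,
                                 offset=offset) for z in st]
        for ra, rb_ in zip(er_rings[:-1], er_rings[1:]):
            b.quad_strip(ra, rb_, ERM_DENDRITE, 1)
    else:
        we = min(1.6 * p.spine_er_radius, zs - e0, e1 - zs)
        s_lo = np.linspace(e0, zs - we, max(1, round((zs - we - e0) / target_e)) + 1)
        s_hi = np.linspace(zs + we, e1, max(1, round((e1 - zs - we) / target_e)) + 1)
        st = np.concatenate([s_lo, s_hi])
        er_rings, er_hole, er_ang = _branch_hole(
            b, n, p.dendrite_er_radius, p.spine_er_radius, zs, st,
            ERM_DENDRITE, 1)
    ce0 = b.add_vertex((0.0, 0.0, e0))
    ce1 = b.add_vertex((0.0, 0.0, e1))
    b.fan(ce0, er_rings[0], ERM_DENDRITE, 1, flip=True)
    b.fan(ce1, er_rings[-1], ERM_DENDRITE, 1)

    if prof is not None:
        y0e = math.sqrt(max(p.dendrite_er_radius**2 - p.spine_er_radius**2, 0.0))
        tube_base = _circle_ring(b, n, p.spine_er_radius, "y", y0e,
                                 center2=(0.0, zs), offset=ring_offset)
        tb_pts = np.array(b.verts)[tube_base]
        tb_ang = np.arctan2(tb_pts[:, 0], -(tb_pts[:, 2] - zs))
        b.zip_loops(er_hole, tube_base, er_ang, tb_ang, ERM_DENDRITE, 1)
        _, y1e, bulb = prof
        tube_len = y1e - y0e
        n_tube = max(2, round(tube_len / 0.1) + 1)
        ys = np.linspace(y0e, y1e, n_tube)
        prev = tube_base
        for y in ys[1:]:
            ring = _circle_ring(b, n, p.spine_er_radius, "y", y,
                                center2=(0.0, zs), offset=ring_offset)
            b.quad_strip(prev, ring, ERM_SPINE, 1)
            prev = ring
        if bulb is None:
            ctip = b.add_vertex((0.0, y1e, zs))
            b.fan(ctip, prev, ERM_SPINE, 1, flip=True)
        else:
            yb, rb_ = bulb
            tip = p.spine_er_length
            n_bulb = max(4, n)
            for y in np.linspace(y1e, tip, n_bulb + 1)[1:-1]:
                r = math.sqrt(max(rb_ * rb_ - (y - yb) ** 2, 0.0))
                ring = _circle_ring(b, n, r, "y", y, center2=(0.0, zs),
                                    offset=ring_offset)
                b.quad_strip(prev, ring, ERM_SPINE, 1)
                prev = ring
            ctip = b.add_vertex((0.0, tip, zs))
            b.fan(ctip, prev, ERM_SPINE, 1, flip=True)

    return SurfaceMesh(
        vertices=np.array(b.verts),
        faces=b.faces,
        labels=b.labels,
        compartment=b.comp,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_obj(mesh: SurfaceMesh, path):
    """Wavefront OBJ with one group per subset label."""
    with open(path, "w") as fh:
        fh.write("# spinecalc surface mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        order = sorted(set(mesh.labels))
        for label in order:
            fh.write(f"g {label}\n")
            for f, l in zip(mesh.faces, mesh.labels):
                if l == label:
                    fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def write_vtk(mesh: SurfaceMesh, path):
    """Legacy ASCII VTK PolyData with subset labels as cell data."""
    order = sorted(set(mesh.labels))
    label_id = {l: i for i, l in enumerate(order)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("spinecalc surface mesh; subsets: "
                 + " ".join(f"{i}={l}" for l, i in label_id.items()) + "\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        size = sum(len(f) + 1 for f in mesh.faces)
        fh.write(f"POLYGONS {len(mesh.faces)} {size}\n")
        for f in mesh.faces:
            fh.write(str(len(f)) + " " + " ".join(str(i) for i in f) + "\n")
        fh.write(f"CELL_DATA {len(mesh.faces)}\n")
        fh.write("SCALARS subset int 1\nLOOKUP_TABLE default\n")
        for l in mesh.labels:
            fh.write(f"{label_id[l]}\n")
        fh.write("SCALARS compartment int 1\nLOOKUP_TABLE default\n")
        for c in mesh.compartment:
            fh.write(f"{c}\n")
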