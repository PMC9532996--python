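"""STL surface generation and measurement.

Generated morphotype surfaces are lofted annular tubes (outer surface of
revolution around each ray's axis, capped at the ends) written as binary
STL for visualization.  Reading supports both binary and ASCII STL; surface
input is used only for *measurement* — bone length and midshaft cortical
thickness — never as a solver mesh.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import MeshError
from .morphology import MorphotypeSpec, SectionProfile

__all__ = [
    "tube_surface",
    "morphotype_surface",
    "write_stl",
    "read_stl",
    "mesh_length",
    "mesh_pair_thickness",
]


def tube_surface(
    length: float,
    profile: SectionProfile,
    surface: str = "outer",
    n_axial: int = 60,
    n_circ: int = 32,
    offset=(0.0, 0.0, 0.0),
) -> trimesh.Trimesh:
    """Closed surface of revolution of one ray's outer or inner radius (mm).

    The tube axis runs along +x from the origin; ``offset`` translates the
    ray laterally.  Ends are capped with triangle fans so the surface is
    watertight.
    """
    stations = np.linspace(0.0, 1.0, n_axial)
    if surface == "outer":
        radii, _ = profile.radii_at(stations)
    elif surface == "inner":
        _, radii = profile.radii_at(stations)
        radii = np.maximum(radii, 1e-6)
    else:
        raise MeshError(f"unknown surface {surface!r}")
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)

    verts = []
    for s, r in zip(stations, radii):
        x = s * length
        verts.append(
            np.column_stack(
                [np.full(n_circ, x), r * np.cos(theta), r * np.sin(theta)]
            )
        )
    verts = np.vstack(verts)

    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps
    centre0 = len(verts)
    centre1 = centre0 + 1
    verts = np.vstack([verts, [[0.0, 0.0, 0.0], [length, 0.0, 0.0]]])
    last = (n_axial - 1) * n_circ
    for j in range(n_circ):
        faces.append((centre0, (j + 1) % n_circ, j))
        faces.append((centre1, last + j, last + (j + 1) % n_circ))

    mesh = trimesh.Trimesh(
        vertices=verts + np.asarray(offset), faces=np.asarray(faces), process=False
    )
    return mesh


def morphotype_surface(spec: MorphotypeSpec, **kwargs) -> trimesh.Trimesh:
    """Outer surfaces of all rays of a morphotype, concatenated."""
    n_rays = spec.n_rays
    offsets = (np.arange(n_rays) - (n_rays - 1) / 2.0) * spec.ray_spacing
    meshes = [
        tube_surface(spec.length, p, offset=(0.0, off, 0.0), **kwargs)
        for p, off in zip(spec.profiles, offsets)
    ]
    return trimesh.util.concatenate(meshes)


def write_stl(mesh: trimesh.Trimesh, path) -> None:
    """Write binary STL."""
    mesh.export(path, file_type="stl")


def read_stl(path) -> trimesh.Trimesh:
    """Read binary or ASCII STL."""
    mesh = trimesh.load_mesh(path, file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshError(f"{path}: not a triangulated surface")
    return mesh


def mesh_length(mesh: trimesh.Trimesh, axis: int = 0) -> float:
    """Bone length: extent of the surface along its long axis (default x)."""
    lo, hi = mesh.bounds[:, axis]
    return float(hi - lo)


def _section_mean_radius(mesh: trimesh.Trimesh, x_mid: float) -> float:
    section = mesh.section(
        plane_origin=[x_mid, 0.0, 0.0], plane_normal=[1.0, 0.0, 0.0]
    )
    if section is None or len(section.vertices) == 0:
        raise MeshError("no cross-section at mid-length; surface open or degenerate")
    pts = section.vertices[:, 1:]
    centre = pts.mean(axis=0)
    return float(np.mean(np.linalg.norm(pts - centre, axis=1)))


def mesh_pair_thickness(outer: trimesh.Trimesh, inner: trimesh.Trimesh) -> float:
    """Mean cortical thickness at mid-length from an outer/inner surface pair.

    Both surfaces are sliced by the transverse plane at the outer surface's
    mid-length; the thickness is the difference of the mean radial distances
    of the two section curves from their centroids.
    """
    lo, hi = outer.bounds[:, 0]
    x_mid = 0.5 * (lo + hi)
    r_out = _section_mean_radius(outer, x_mid)
    r_in = _section_mean_radius(inner, x_mid)
    t = r_out - r_in
    if t <= 0.0:
        raise MeshError("inner surface is not inside the outer surface at midshaft")
    return t
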