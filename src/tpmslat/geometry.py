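"""Cylindrical shell-type TPMS lattice generation and geometric descriptors.

A lattice design is a triply periodic minimal surface (TPMS) level set —
Gyroid, Schwarz Diamond or Split-P — thickened into a sheet solid of uniform
metric thickness and clipped to a cylindrical envelope (axis = Z, base at
z = 0).  Descriptors are computed on a voxelization of the solid:

* relative density (RD, %): solid volume over envelope volume,
* porosity (%): 100 − RD,
* surface area (mm²): area of the triangulated solid boundary,
* SA/VR (1/mm): surface area over *solid* (material) volume.

Level-set expressions (X = 2πx/Lx etc., after rotating coordinates about the
X axis by the design's rotation angle):

* gyroid:   sin X cos Y + sin Y cos Z + sin Z cos X
* diamond:  sin X sin Y sin Z + sin X cos Y cos Z
            + cos X sin Y cos Z + cos X cos Y sin Z
* split_p:  1.1 [sin 2X sin Z cos Y + sin 2Y sin X cos Z + sin 2Z sin Y cos X]
            − 0.2 [cos 2X cos 2Y + cos 2Y cos 2Z + cos 2Z cos 2X]
            − 0.4 [cos 2X + cos 2Y + cos 2Z]

These are the standard published forms; coefficients live in
``SPLIT_P_COEFFS`` so alternates can be swapped.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

SURFACE_TYPES = ("gyroid", "diamond", "split_p")

#: Split-P level-set coefficients (amplitudes of the three term groups).
SPLIT_P_COEFFS = (1.1, -0.2, -0.4)

#: Central-difference step for field gradients, as a fraction of the
#: smallest cell size.
GRADIENT_STEP_FRACTION = 1e-3

#: Below this gradient norm the metric-distance estimate is unreliable and
#: membership falls back to a raw field band |phi| <= pi * t / L_min
#: (the first-order field change over a metric distance t near a flat
#: region of the unit-amplitude level set).
GRADIENT_NORM_TOL = 1e-6

#: Refuse voxel grids beyond this many cells (~1.6 GB of float64 scratch).
MAX_VOXELS = int(2e8)


class UnsupportedSurfaceError(ValueError):
    """Raised for a surface type outside ``SURFACE_TYPES``."""


class EmptyMeshError(ValueError):
    """Raised when an isosurface extraction yields no triangles."""


class ResolutionError(MemoryError):
    """Raised when a requested voxel grid exceeds the memory budget."""


@dataclass(frozen=True)
class LatticeDesign:
    """The seven-parameter cylindrical TPMS design point.

    Lengths in mm, rotation about the X axis in degrees.  ``full_solid``
    bypasses the thickness test entirely (every in-envelope point is solid);
    it exists for degenerate/validation cases and skips the
    thickness < min cell size invariant.
    """

    surface_type: str
    cell_size_x: float
    cell_size_y: float
    cell_size_z: float
    thickness: float
    rotation_deg: float
    height: float
    diameter: float
    full_solid: bool = False

    def __post_init__(self) -> None:
        if self.surface_type not in SURFACE_TYPES:
            raise UnsupportedSurfaceError(
                f"surface_type {self.surface_type!r} not in {SURFACE_TYPES}"
            )
        for name in ("cell_size_x", "cell_size_y", "cell_size_z",
                     "thickness", "height", "diameter"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.rotation_deg < 90):
            raise ValueError("rotation_deg must lie in [0, 90)")
        if not self.full_solid and self.thickness >= self.min_cell_size:
            raise ValueError(
                "thickness must be smaller than the smallest cell size "
                "(use full_solid=True for the degenerate solid cylinder)"
            )

    @property
    def cell_sizes(self) -> np.ndarray:
        return np.array([self.cell_size_x, self.cell_size_y, self.cell_size_z])

    @property
    def min_cell_size(self) -> float:
        return min(self.cell_size_x, self.cell_size_y, self.cell_size_z)

    @property
    def aspect_ratio(self) -> float:
        return self.height / self.diameter

    def to_dict(self) -> dict:
        return {
            "surface_type": self.surface_type,
            "cell_size_x": self.cell_size_x,
            "cell_size_y": self.cell_size_y,
            "cell_size_z": self.cell_size_z,
            "thickness": self.thickness,
            "rotation_deg": self.rotation_deg,
            "height": self.height,
            "diameter": self.diameter,
        }


@dataclass
class VoxelGrid:
    """Axis-aligned occupancy grid; cell centers at origin + (i + 1/2)·spacing."""

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray  # boolean, shape (nx, ny, nz)

    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    @property
    def solid_volume(self) -> float:
        return float(self.occupancy.sum()) * self.spacing**3


@dataclass
class GeometricDescriptors:
    relative_density: float  # percent
    surface_area: float      # mm^2
    sa_vr: float             # 1/mm
    porosity: float          # percent
    spacing: float           # mm, voxel pitch used

    def to_dict(self) -> dict:
        return {
            "relative_density": self.relative_density,
            "surface_area": self.surface_area,
            "sa_vr": self.sa_vr,
            "porosity": self.porosity,
            "spacing": self.spacing,
        }


def _rotate_about_x(points: np.ndarray, rotation_deg: float) -> np.ndarray:
    if rotation_deg == 0:
        return points
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty_like(points, dtype=float)
    out[..., 0] = points[..., 0]
    out[..., 1] = c * points[..., 1] - s * points[..., 2]
    out[..., 2] = s * points[..., 1] + c * points[..., 2]
    return out


def implicit_field(surface_type: str, points: np.ndarray,
                   cell_sizes, rotation_deg: float = 0.0) -> np.ndarray:
    """Evaluate the TPMS level-set field at ``points`` (..., 3) in mm.

    Coordinates are rotated about X by ``rotation_deg`` and phase-scaled by
    2π/cell_size per axis before the trigonometric expression is evaluated.
    Periodic with period cell_size along each (unrotated) axis.
    """
    if surface_type not in SURFACE_TYPES:
        raise UnsupportedSurfaceError(
            f"surface_type {surface_type!r} not in {SURFACE_TYPES}"
        )
    points = np.asarray(points, dtype=float)
    scalar_input = points.ndim == 1
    p = np.atleast_2d(points)
    p = _rotate_about_x(p, rotation_deg)
    L = np.asarray(cell_sizes, dtype=float)
    X, Y, Z = (2.0 * np.pi * p[..., i] / L[i] for i in range(3))

    if surface_type == "gyroid":
        out = np.sin(X) * np.cos(Y) + np.sin(Y) * np.cos(Z) + np.sin(Z) * np.cos(X)
    elif surface_type == "diamond":
        out = (np.sin(X) * np.sin(Y) * np.sin(Z)
               + np.sin(X) * np.cos(Y) * np.cos(Z)
               + np.cos(X) * np.sin(Y) * np.cos(Z)
               + np.cos(X) * np.cos(Y) * np.sin(Z))
    else:  # split_p
        a, b, c = SPLIT_P_COEFFS
        out = (a * (np.sin(2 * X) * np.sin(Z) * np.cos(Y)
                    + np.sin(2 * Y) * np.sin(X) * np.cos(Z)
                    + np.sin(2 * Z) * np.sin(Y) * np.cos(X))
               + b * (np.cos(2 * X) * np.cos(2 * Y)
                      + np.cos(2 * Y) * np.cos(2 * Z)
                      + np.cos(2 * Z) * np.cos(2 * X))
               + c * (np.cos(2 * X) + np.cos(2 * Y) + np.cos(2 * Z)))
    return out[0] if scalar_input else out


def _field_and_gradient(design: LatticeDesign, points: np.ndarray):
    """phi and its central-difference gradient at ``points`` (n, 3)."""
    h = GRADIENT_STEP_FRACTION * design.min_cell_size
    args = (design.surface_type, design.cell_sizes, design.rotation_deg)

    def f(p):
        return implicit_field(args[0], p, args[1], args[2])

    phi = f(points)
    grad = np.empty_like(points, dtype=float)
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = h
        grad[:, axis] = (f(points + e) - f(points - e)) / (2 * h)
    return phi, grad


def shell_distance(design: LatticeDesign, points: np.ndarray) -> np.ndarray:
    """First-order metric distance |phi| / ||grad phi|| to the level set (mm).

    Where the gradient vanishes (critical points of the field) the estimate
    is replaced by a bounded field-band distance so membership never divides
    by zero: the fallback maps |phi| through the nominal field slope
    2π/L_min of the unit-amplitude level set.
    """
    phi, grad = _field_and_gradient(design, points)
    gnorm = np.linalg.norm(grad, axis=-1)
    nominal_slope = 2.0 * np.pi / design.min_cell_size
    dist = np.abs(phi) / np.maximum(gnorm, GRADIENT_NORM_TOL)
    fallback = np.abs(phi) / nominal_slope
    return np.where(gnorm < GRADIENT_NORM_TOL, fallback, dist)


def envelope_distance(design: LatticeDesign, points: np.ndarray) -> np.ndarray:
    """Signed distance to the cylindrical envelope (negative inside)."""
    r = np.sqrt(points[..., 0] ** 2 + points[..., 1] ** 2)
    return np.maximum.reduce([
        r - design.diameter / 2.0,
        -points[..., 2],
        points[..., 2] - design.height,
    ])


def signed_thickness_test(design: LatticeDesign, points: np.ndarray) -> np.ndarray:
    """True where a point lies in the shell solid inside the envelope."""
    points = np.asarray(points, dtype=float)
    scalar_input = points.ndim == 1
    p = np.atleast_2d(points)
    in_env = envelope_distance(design, p) <= 0.0
    if design.full_solid:
        out = in_env
    else:
        out = np.zeros(len(p), dtype=bool)
        if in_env.any():
            d = shell_distance(design, p[in_env])
            out[in_env] = d <= design.thickness / 2.0
    return bool(out[0]) if scalar_input else out


def _grid_axes(design: LatticeDesign, spacing: float):
    r = design.diameter / 2.0
    nx = ny = int(np.ceil(design.diameter / spacing))
    nz = int(np.ceil(design.height / spacing))
    origin = np.array([-r, -r, 0.0])
    return origin, (nx, ny, nz)


def _check_spacing(design: LatticeDesign, spacing: float) -> None:
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if design.full_solid:
        return
    if spacing > design.thickness / 2.0:
        raise ValueError(
            f"spacing {spacing} exceeds thickness/2 = {design.thickness / 2.0}; "
            "the shell would be under-resolved"
        )
    if spacing > design.thickness / 4.0:
        warnings.warn(
            f"spacing {spacing} above thickness/4 = {design.thickness / 4.0}; "
            "descriptors may be poorly converged", stacklevel=3
        )


def voxelize(design: LatticeDesign, spacing: float) -> VoxelGrid:
    """Sample shell membership at voxel centers on a grid covering the envelope."""
    _check_spacing(design, spacing)
    origin, shape = _grid_axes(design, spacing)
    n = int(np.prod(shape))
    if n > MAX_VOXELS:
        suggested = spacing * (n / MAX_VOXELS) ** (1 / 3)
        raise ResolutionError(
            f"{n} voxels exceed budget {MAX_VOXELS}; try spacing >= {suggested:.4g} mm"
        )
    ax = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing for i in range(3)]
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    occ = signed_thickness_test(design, pts).reshape(shape)
    return VoxelGrid(origin=origin, spacing=spacing, occupancy=occ)


def mesh_from_field(field_fn, bounds, spacing: float) -> trimesh.Trimesh:
    """Triangulate the zero level set of ``field_fn`` (solid where field <= 0).

    ``bounds`` is ((xmin, ymin, zmin), (xmax, ymax, zmax)) in mm.  The grid is
    padded by one voxel of positive field so solids touching the bounds are
    closed.  Degenerate faces are dropped.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 3, 2)
    ax = [lo[i] + (np.arange(shape[i]) - 1.0) * spacing for i in range(3)]
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    vol = np.asarray(field_fn(pts), dtype=float).reshape(shape)
    # pad layer is forced outside so marching cubes closes the boundary
    big = max(1.0, np.nanmax(np.abs(vol)))
    vol[[0, -1], :, :] = big
    vol[:, [0, -1], :] = big
    vol[:, :, [0, -1]] = big
    if vol.min() > 0 or vol.max() <= 0:
        raise EmptyMeshError("field has no zero crossing inside the bounds")
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(spacing,) * 3)
    verts = verts + (lo - spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    if len(mesh.faces) == 0:
        raise EmptyMeshError("isosurface produced no non-degenerate triangles")
    return mesh


def solid_field(design: LatticeDesign, points: np.ndarray) -> np.ndarray:
    """Signed indicator field of the clipped shell solid (<= 0 inside).

    max of (metric shell distance − t/2) and the envelope distance; its zero
    level set is the boundary of the solid including the cylindrical and
    planar cut faces.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    env = envelope_distance(design, points)
    if design.full_solid:
        return env
    shell = shell_distance(design, points) - design.thickness / 2.0
    return np.maximum(shell, env)


def extract_surface(design: LatticeDesign, spacing: float) -> trimesh.Trimesh:
    """Triangulated boundary of the shell solid clipped to the envelope."""
    _check_spacing(design, spacing)
    r = design.diameter / 2.0
    bounds = ((-r, -r, 0.0), (r, r, design.height))
    return mesh_from_field(lambda p: solid_field(design, p), bounds, spacing)


def compute_descriptors(design: LatticeDesign, spacing: float) -> GeometricDescriptors:
    """RD, porosity, surface area and SA/VR at the given voxel pitch.

    RD uses the in-envelope voxel count as the envelope volume so the
    degenerate full solid reads exactly 100%; surface area comes from the
    extracted isosurface; SA/VR divides by the solid (material) volume.
    """
    grid = voxelize(design, spacing)
    ax = [grid.origin[i] + (np.arange(grid.shape[i]) + 0.5) * spacing
          for i in range(3)]
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    in_env = (envelope_distance(design, pts) <= 0.0).reshape(grid.shape)
    n_env = int(in_env.sum())
    n_solid = int(grid.occupancy.sum())
    rd = 100.0 * n_solid / n_env
    solid_volume = n_solid * spacing**3
    mesh = extract_surface(design, spacing)
    area = float(mesh.area)
    return GeometricDescriptors(
        relative_density=rd,
        surface_area=area,
        sa_vr=area / solid_volume if solid_volume > 0 else 0.0,
        porosity=100.0 - rd,
        spacing=spacing,
    )


def export_stl(mesh: trimesh.Trimesh, path) -> None:
    """Write a binary little-endian STL (units mm); refuses an empty mesh."""
    if mesh is None or len(mesh.faces) == 0:
        raise EmptyMeshError("refusing to export an empty mesh")
    try:
        data = mesh.export(file_type="stl")
        with open(path, "wb") as fh:
            fh.write(data)
    except OSError as exc:
        raise OSError(f"STL export to {path!r} failed: {exc}") from exc
    # header arithmetic: 80-byte header + uint32 count + 50 bytes/triangle
    with open(path, "rb") as fh:
        fh.seek(80)
        (count,) = struct.unpack("<I", fh.read(4))
    if count != len(mesh.faces):
        raise IOError(
            f"STL triangle count {count} does not match mesh {len(mesh.faces)}"
        )


__all__ = [
    "SURFACE_TYPES", "SPLIT_P_COEFFS", "LatticeDesign", "VoxelGrid",
    "GeometricDescriptors", "UnsupportedSurfaceError", "EmptyMeshError",
    "ResolutionError", "implicit_field", "shell_distance", "envelope_distance",
    "signed_thickness_test", "voxelize", "mesh_from_field", "solid_field",
    "extract_surface", "compute_descriptors", "export_stl",
]
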