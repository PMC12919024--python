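"""Mesh pose normalization, spherical parameterization, and SPHARM models.

A genus-0 cell surface mesh is centered on its centroid, rotated so the
area-weighted mean normal of its basal facets (face normals with z < -0.8)
points along -z, and spun about z so the larger share of enclosed volume has
positive x.  The pre-alignment centroid height classifies the cell as
deformed (> 10 um) or non-deformed.

The aligned surface is resampled by nearest-neighbour lookup onto a spherical
grid of resolution pi/64 in both polar and azimuthal angle (64 rings x 128
columns + 2 poles = 8,194 vertices), and each Cartesian coordinate function
over the sphere is fit independently with complex spherical harmonics
Y_l^m up to a maximum degree Lmax by linear least squares:

    x(theta, phi) = sum_{l=0}^{Lmax} sum_{m=-l}^{l} c_l^{x,m} Y_l^m(theta, phi)

and likewise for y and z.  At Lmax=10 each coordinate carries (10+1)^2 = 121
complex coefficients, i.e. 726 real features per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .geometry2d import FitDiagnostics, _information_criteria

__all__ = [
    "SphericalGrid",
    "SPHARMShape",
    "align_mesh",
    "label_deformation",
    "spherical_parameterize",
    "fit_spharm",
    "reconstruct_spharm",
    "select_degree",
    "spharm_to_frame",
    "frame_to_spharm",
]

BASAL_NORMAL_Z_THRESHOLD = -0.8
DEFORMED_HEIGHT_UM = 10.0
GRID_RESOLUTION = np.pi / 64  # -> 64 polar rings x 128 azimuthal columns


# ---------------------------------------------------------------------------
# Alignment and deformation labeling
# ---------------------------------------------------------------------------

def _as_mesh(m) -> trimesh.Trimesh:
    if isinstance(m, trimesh.Trimesh):
        return m
    vertices, faces = m
    return trimesh.Trimesh(vertices=np.asarray(vertices, float),
                           faces=np.asarray(faces, int), process=False)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return trimesh.transformations.rotation_matrix(np.pi, axis)[:3, :3]
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _clip_triangle_halfplane(tri: np.ndarray) -> list[np.ndarray]:
    """Clip one triangle to x >= 0 (Sutherland-Hodgman), re-fanned to triangles."""
    poly = []
    for i in range(3):
        cur, nxt = tri[i], tri[(i + 1) % 3]
        if cur[0] >= 0:
            poly.append(cur)
        if (cur[0] >= 0) != (nxt[0] >= 0):
            t = cur[0] / (cur[0] - nxt[0])
            poly.append(cur + t * (nxt - cur))
    if len(poly) < 3:
        return []
    return [np.array([poly[0], poly[j], poly[j + 1]])
            for j in range(1, len(poly) - 1)]


def _halfspace_volume_positive_x(mesh: trimesh.Trimesh) -> float:
    """Volume of the mesh interior with x > 0, via the divergence (cone) formula.

    Triangles are clipped against the plane x = 0, which passes through the
    origin used as the cone apex, so the planar cap contributes no volume and
    the clipped surface alone determines the half-space volume.
    """
    tris = mesh.triangles
    crossing = (tris[:, :, 0].min(axis=1) < 0) & (tris[:, :, 0].max(axis=1) > 0)
    inside = tris[:, :, 0].min(axis=1) >= 0
    vol = np.einsum(
        "ij,ij->i", tris[inside, 0],
        np.cross(tris[inside, 1], tris[inside, 2])).sum()
    for tri in tris[crossing]:
        for piece in _clip_triangle_halfplane(tri):
            vol += float(piece[0] @ np.cross(piece[1], piece[2]))
    return abs(vol) / 6.0


def align_mesh(
    m, basal_threshold: float = BASAL_NORMAL_Z_THRESHOLD
) -> tuple[trimesh.Trimesh, float]:
    """Pose-normalize a watertight mesh; returns (aligned mesh, centroid height).

    The centroid height (z of the volume centroid, in um, recorded before any
    transform) is the feature used for deformed/non-deformed labeling.
    Alignment: center on the centroid; rotate the area-weighted mean basal
    normal to (0, 0, -1); spin about z so the xy principal axis lies along x
    and the larger enclosed volume sits at x > 0.
    """
    mesh = _as_mesh(m).copy()
    if not mesh.is_watertight:
        raise ValueError("mesh must be watertight")
    centroid = mesh.center_mass
    centroid_height = float(centroid[2])

    mesh.apply_translation(-centroid)

    # basal facets move across the threshold as the mesh rotates, so aligning
    # their mean normal is a fixed-point iteration (converges in a few steps
    # for any mesh with a genuinely flat base; idempotence follows)
    for _ in range(100):
        basal = mesh.face_normals[:, 2] < basal_threshold
        if not basal.any():
            raise ValueError(
                f"no basal facets with normal z < {basal_threshold}; "
                "consider relaxing the threshold"
            )
        w = mesh.area_faces[basal]
        mean_normal = (mesh.face_normals[basal] * w[:, None]).sum(axis=0)
        mean_normal /= np.linalg.norm(mean_normal)
        if np.linalg.norm(mean_normal - [0.0, 0.0, -1.0]) < 1e-9:
            break
        R = _rotation_between(mean_normal, np.array([0.0, 0.0, -1.0]))
        mesh.apply_transform(np.vstack([np.hstack([R, np.zeros((3, 1))]),
                                        [0, 0, 0, 1]]))

    # z-spin: xy principal axis of the vertex scatter to x
    xy = mesh.vertices[:, :2]
    cov = np.cov((xy - xy.mean(axis=0)).T, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] > 1e-12 * max(evals[1], 1e-300):
        major = evecs[:, 1]
        ang = np.arctan2(major[1], major[0])
        # the axis is directionless: stay within (-pi/2, pi/2] so an aligned
        # mesh is not spun by pi
        if ang > np.pi / 2:
            ang -= np.pi
        elif ang <= -np.pi / 2:
            ang += np.pi
        if abs(ang) > 1e-12:
            mesh.apply_transform(
                trimesh.transformations.rotation_matrix(-ang, [0, 0, 1]))
    # flip so the larger enclosed volume has x > 0
    vol_pos = _halfspace_volume_positive_x(mesh)
    if vol_pos < 0.5 * abs(mesh.volume) - 1e-9:
        mesh.apply_transform(
            trimesh.transformations.rotation_matrix(np.pi, [0, 0, 1]))
    mesh.apply_translation(-mesh.center_mass)
    return mesh, centroid_height


def label_deformation(centroid_height: float,
                      cutoff_um: float = DEFORMED_HEIGHT_UM) -> str:
    """Classify a cell by pre-alignment centroid height; ties go non-deformed."""
    return "deformed" if centroid_height > cutoff_um else "non-deformed"


# ---------------------------------------------------------------------------
# Spherical grid and parameterization
# ---------------------------------------------------------------------------

@dataclass
class SphericalGrid:
    """Surface samples on the pi/64 polar/azimuthal grid (8,194 vertices).

    Rings sit at theta_j = (j - 1/2) * pi/64 (uniform pi/64 spacing, no pole
    collision); columns at phi_i = i * pi/64 for i = 0..127; the two poles are
    explicit extra samples at theta = 0 and pi.
    """

    theta: np.ndarray  # (M,) polar angle in [0, pi]
    phi: np.ndarray  # (M,) azimuthal angle in [0, 2 pi)
    vertices: np.ndarray  # (M, 3) Cartesian surface points
    n_rings: int = 64
    n_cols: int = 128

    @property
    def n_vertices(self) -> int:
        return len(self.theta)

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.vertices, axis=1)


def grid_directions(n_rings: int = 64, n_cols: int = 128
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) of the sampling grid incl. poles; pole first/last."""
    rings = (np.arange(1, n_rings + 1) - 0.5) * (np.pi / n_rings)
    cols = np.arange(n_cols) * (2.0 * np.pi / n_cols)
    tt, pp = np.meshgrid(rings, cols, indexing="ij")
    theta = np.concatenate([[0.0], tt.ravel(), [np.pi]])
    phi = np.concatenate([[0.0], pp.ravel(), [0.0]])
    return theta, phi


def spherical_parameterize(
    mesh: trimesh.Trimesh, n_rings: int = 64, n_cols: int = 128
) -> SphericalGrid:
    """Resample an aligned, star-convex surface onto the spherical grid.

    For every grid direction the output vertex is the mesh vertex whose
    centroid-relative direction is angularly nearest (maximum dot product,
    implemented as a nearest-neighbour query on unit vectors).  Warns if the
    mesh is visibly non-star-convex about the origin.
    """
    mesh = _as_mesh(mesh)
    if not _origin_inside(mesh):
        raise ValueError("origin lies outside the mesh; align/center it first")
    v = np.asarray(mesh.vertices, float)
    r = np.linalg.norm(v, axis=1)
    if (r < 1e-12).any():
        raise ValueError("mesh vertex coincides with the origin")
    units = v / r[:, None]

    theta, phi = grid_directions(n_rings, n_cols)
    st = np.sin(theta)
    dirs = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    # angular NN == Euclidean NN on the unit sphere
    _, idx = cKDTree(units).query(dirs)
    grid = SphericalGrid(theta=theta, phi=phi, vertices=v[idx],
                         n_rings=n_rings, n_cols=n_cols)

    # fold check: the mapped radius should vary smoothly for star-convex input
    if not _looks_star_convex(mesh):
        warnings.warn("mesh may not be star-convex; spherical map may fold",
                      stacklevel=2)
    return grid


def _origin_inside(mesh: trimesh.Trimesh) -> bool:
    """Winding number of the surface about the origin (van Oosterom solid angles)."""
    tri = mesh.triangles
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    num = np.einsum("ij,ij->i", a, np.cross(b, c))
    den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
           + np.einsum("ij,ij->i", a, c) * lb
           + np.einsum("ij,ij->i", b, c) * la)
    winding = np.sum(2.0 * np.arctan2(num, den)) / (4.0 * np.pi)
    return bool(abs(winding) > 0.5)


def _looks_star_convex(mesh: trimesh.Trimesh) -> bool:
    """Sufficient check: every outward face normal points away from the origin."""
    centroids = mesh.triangles_center
    dots = np.einsum("ij,ij->i", mesh.face_normals, centroids)
    return bool((dots > 0).mean() > 0.99)


# ---------------------------------------------------------------------------
# SPHARM fitting
# ---------------------------------------------------------------------------

@dataclass
class SPHARMShape:
    """Complex coefficients c_l^m per Cartesian coordinate, l = 0..l_max."""

    l_max: int
    coeffs: np.ndarray  # (3, (l_max+1)^2) complex; rows x, y, z

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.shape != (3, (self.l_max + 1) ** 2):
            raise ValueError("coefficient array must be (3, (l_max+1)^2)")

    @property
    def n_coeffs_per_coord(self) -> int:
        return (self.l_max + 1) ** 2

    @property
    def n_features(self) -> int:
        return 3 * self.n_coeffs_per_coord * 2

    def flatten(self) -> np.ndarray:
        """Real feature vector: [Re, Im] interleaved per coefficient, x|y|z."""
        out = np.empty(self.n_features)
        flat = self.coeffs.ravel()
        out[0::2] = flat.real
        out[1::2] = flat.imag
        return out

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "SPHARMShape":
        flat = np.asarray(flat, dtype=float)
        n_c = len(flat) // 6
        l_max = int(round(np.sqrt(n_c))) - 1
        if 3 * (l_max + 1) ** 2 * 2 != len(flat):
            raise ValueError("flattened length must be 6*(l_max+1)^2")
        coeffs = (flat[0::2] + 1j * flat[1::2]).reshape(3, n_c)
        return cls(l_max=l_max, coeffs=coeffs)

    def coefficient(self, coord: str, l: int, m: int) -> complex:
        i = {"x": 0, "y": 1, "z": 2}[coord]
        return complex(self.coeffs[i, l * (l + 1) + m])


def lm_pairs(l_max: int) -> list[tuple[int, int]]:
    """(l, m) in basis order: l ascending, m = -l..l (index l(l+1)+m)."""
    return [(l, m) for l in range(l_max + 1) for m in range(-l, l + 1)]


def spharm_basis(theta: np.ndarray, phi: np.ndarray, l_max: int) -> np.ndarray:
    """Design matrix of Y_l^m(theta, phi), shape (len(theta), (l_max+1)^2)."""
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    B = np.empty((len(theta), (l_max + 1) ** 2), dtype=complex)
    for j, (l, m) in enumerate(lm_pairs(l_max)):
        B[:, j] = sph_harm_y(l, m, theta, phi)
    return B


def fit_spharm(
    grid: SphericalGrid, l_max: int
) -> tuple[SPHARMShape, FitDiagnostics]:
    """Complex least-squares SPHARM fit of x, y, z over the grid samples.

    Each coordinate is solved independently against the shared basis matrix;
    diagnostics pool the squared residual moduli of all three coordinates
    (N = 3 * grid size real observations, p = 6 * (l_max+1)^2 real parameters).
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    n_basis = (l_max + 1) ** 2
    if n_basis > grid.n_vertices:
        raise ValueError(
            f"underdetermined: {n_basis} basis functions for "
            f"{grid.n_vertices} grid points"
        )
    B = spharm_basis(grid.theta, grid.phi, l_max)
    target = grid.vertices.astype(complex)
    coef, _, _, _ = np.linalg.lstsq(B, target, rcond=None)
    resid = target - B @ coef
    rss = float(np.sum(np.abs(resid) ** 2))
    n_obs = 3 * grid.n_vertices
    n_params = 6 * n_basis
    aic, bic = _information_criteria(rss, n_obs, n_params)
    return (SPHARMShape(l_max=l_max, coeffs=coef.T.copy()),
            FitDiagnostics(rss, aic, bic, n_params, n_obs))


def evaluate_spharm(s: SPHARMShape, theta: np.ndarray, phi: np.ndarray,
                    imag_tol: float = 1e-6) -> np.ndarray:
    """Evaluate the truncated sums; returns real (M, 3) coordinates."""
    B = spharm_basis(theta, phi, s.l_max)
    xyz = B @ s.coeffs.T
    max_imag = float(np.abs(xyz.imag).max()) if xyz.size else 0.0
    if max_imag > imag_tol:
        warnings.warn(
            f"imaginary residue {max_imag:.2e} exceeds {imag_tol:.0e}; "
            "input coefficients may not describe a real surface",
            stacklevel=2,
        )
    return xyz.real


def grid_faces(n_rings: int = 64, n_cols: int = 128) -> np.ndarray:
    """Triangulation of the grid topology (pole fans + quad strips)."""
    def ring_vertex(j, i):
        return 1 + j * n_cols + (i % n_cols)

    north, south = 0, 1 + n_rings * n_cols
    faces = []
    for i in range(n_cols):
        faces.append([north, ring_vertex(0, i), ring_vertex(0, i + 1)])
    for j in range(n_rings - 1):
        for i in range(n_cols):
            a, b = ring_vertex(j, i), ring_vertex(j, i + 1)
            c, d = ring_vertex(j + 1, i), ring_vertex(j + 1, i + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    for i in range(n_cols):
        faces.append([south, ring_vertex(n_rings - 1, i + 1),
                      ring_vertex(n_rings - 1, i)])
    return np.asarray(faces, dtype=int)


def reconstruct_spharm(
    s: SPHARMShape, n_rings: int = 64, n_cols: int = 128
) -> trimesh.Trimesh:
    """Evaluate the model on the sampling grid and triangulate it."""
    theta, phi = grid_directions(n_rings, n_cols)
    xyz = evaluate_spharm(s, theta, phi)
    return trimesh.Trimesh(vertices=xyz, faces=grid_faces(n_rings, n_cols),
                           process=False)


def select_degree(
    mesh: trimesh.Trimesh, l_max_max: int,
    n_rings: int = 64, n_cols: int = 128,
) -> pd.DataFrame:
    """Fit at every degree 0..l_max_max and tabulate (l, rss, aic, bic)."""
    grid = spherical_parameterize(mesh, n_rings, n_cols)
    rows = []
    for l in range(l_max_max + 1):
        if (l + 1) ** 2 > grid.n_vertices:
            warnings.warn(f"skipping underdetermined l={l}", stacklevel=2)
            continue
        _, diag = fit_spharm(grid, l)
        rows.append({"l": l, "rss": diag.rss, "aic": diag.aic,
                     "bic": diag.bic})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def spharm_to_frame(shapes: dict[str, SPHARMShape]) -> pd.DataFrame:
    """Tidy coefficient table: cell_id, coord, l, m, real, imag."""
    rows = []
    for cell_id, s in shapes.items():
        for ci, coord in enumerate("xyz"):
            for j, (l, m) in enumerate(lm_pairs(s.l_max)):
                c = s.coeffs[ci, j]
                rows.append({"cell_id": cell_id, "coord": coord, "l": l,
                             "m": m, "real": c.real, "imag": c.imag})
    return pd.DataFrame(rows)


def frame_to_spharm(df: pd.DataFrame) -> dict[str, SPHARMShape]:
    out: dict[str, SPHARMShape] = {}
    for cell_id, grp in df.groupby("cell_id", sort=False):
        l_max = int(grp["l"].max())
        coeffs = np.zeros((3, (l_max + 1) ** 2), dtype=complex)
        ci = {"x": 0, "y": 1, "z": 2}
        for _, row in grp.iterrows():
            j = int(row["l"]) * (int(row["l"]) + 1) + int(row["m"])
            coeffs[ci[row["coord"]], j] = row["real"] + 1j * row["imag"]
        out[str(cell_id)] = SPHARMShape(l_max=l_max, coeffs=coeffs)
    return out
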