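"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here touches real microscopy: boundaries are star-shaped radius
functions (base ellipse + Gaussian bump protrusions), 3-D cells are displaced
icospheres flattened against a basal plane, and fiber images are sinusoidal
stripe patterns.  Each generator is driven by a single integer seed and the
ground truth (class labels, elongation, stripe orientation, centroid height)
is returned alongside the data, so downstream fits can be checked against
what was actually synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

from .geometry2d import Boundary2D, write_boundaries_csv
from .geometry3d import DEFORMED_HEIGHT_UM, label_deformation

__all__ = [
    "ShapePopulationSpec",
    "FiberImageSpec",
    "make_boundary",
    "make_boundary_population",
    "make_mesh",
    "make_mesh_population",
    "make_fiber_image",
    "save_population",
]

DEFAULT_CONDITIONS_2D = ("soft", "stiff")
DEFAULT_CONDITIONS_3D = ("non-deformed", "deformed")


@dataclass
class ShapePopulationSpec:
    """Parameters of a synthetic cell population.

    Two-class populations differ in their elongation distribution (class j
    centered at the j-th quantile of ``elongation_range``), which gives a
    morphology-only classifier a constructed, known separation.  The scalar
    "DOA-like" feature is drawn in [0, 1] with a class-dependent mean.
    """

    n_cells: int = 200
    class_fractions: tuple[float, ...] = (0.5, 0.5)
    elongation_range: tuple[float, float] = (1.0, 3.0)
    protrusion_count_range: tuple[int, int] = (3, 6)
    protrusion_amplitude: float = 2.0  # um
    noise_sd: float = 0.2  # um
    seed: int = 0
    base_radius_um: float = 10.0
    class_spread: float = 0.15  # sd of per-cell elongation around class mean

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be non-negative")
        lo, hi = self.elongation_range
        if not (0 < lo <= hi):
            raise ValueError("elongation_range must satisfy 0 < low <= high")
        plo, phi_ = self.protrusion_count_range
        if not (0 <= plo <= phi_):
            raise ValueError("protrusion_count_range must satisfy 0 <= low <= high")
        if self.protrusion_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        if self.base_radius_um <= 0:
            raise ValueError("base_radius_um must be positive")
        if self.noise_sd + self.protrusion_amplitude >= self.base_radius_um:
            raise ValueError(
                "spec would produce zero-area shapes: "
                "noise_sd + protrusion_amplitude must stay below base_radius_um"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_fractions)


@dataclass
class FiberImageSpec:
    """Sinusoidal stripe image emulating aligned stress fibers."""

    width: int = 128
    height: int = 128
    stripe_period: float = 12.0  # px
    orientation: float = 0.0  # radians; 0 -> intensity varies along y only
    contrast: float = 1000.0
    background_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("image must be at least 32x32")
        if self.stripe_period < 2:
            raise ValueError("stripe_period must be >= 2 px")
        if self.contrast < 0 or self.background_noise_sd < 0:
            raise ValueError("contrast and noise must be non-negative")


# ---------------------------------------------------------------------------
# 2-D boundaries
# ---------------------------------------------------------------------------

def _ellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def make_boundary(
    rng: np.random.Generator,
    elongation: float,
    n_protrusions: int,
    protrusion_amplitude: float,
    noise_sd: float,
    base_radius: float = 10.0,
    n_points: int = 128,
) -> Boundary2D:
    """One star-shaped cell outline r(theta) = ellipse + Gaussian bumps.

    The ellipse has aspect ratio ``elongation`` at constant a*b = R^2, so
    shapes of different elongation enclose comparable areas.  Star-shapedness
    (hence simplicity of the polygon) is guaranteed by construction as long as
    r stays positive, which the population spec enforces.
    """
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    a = base_radius * np.sqrt(elongation)
    b = base_radius / np.sqrt(elongation)
    r = _ellipse_radius(theta, a, b)
    for _ in range(n_protrusions):
        center = rng.uniform(0.0, 2.0 * np.pi)
        width = rng.uniform(0.12, 0.3)
        amp = protrusion_amplitude * rng.uniform(0.6, 1.0)
        d = np.angle(np.exp(1j * (theta - center)))
        r = r + amp * np.exp(-0.5 * (d / width) ** 2)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=n_points)
    r = np.maximum(r, 0.05 * base_radius)
    return Boundary2D(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def _class_means(spec: ShapePopulationSpec) -> np.ndarray:
    lo, hi = spec.elongation_range
    k = spec.n_classes
    if k == 1:
        return np.array([(lo + hi) / 2.0])
    return lo + (hi - lo) * np.arange(k) / (k - 1)


def make_boundary_population(
    spec: ShapePopulationSpec,
    condition_names: tuple[str, ...] | None = None,
) -> list[tuple[Boundary2D, str, float]]:
    """Population of (boundary, condition label, DOA-like scalar) triples.

    Class j draws its elongation around the j-th point of the elongation
    range and its scalar feature around mean 0.25 + 0.5*j/(k-1), clipped to
    [0, 1]; both separations are the constructed ground truth downstream
    classifiers are checked against.
    """
    if condition_names is None:
        condition_names = (DEFAULT_CONDITIONS_2D if spec.n_classes == 2
                           else tuple(f"class{j}" for j in range(spec.n_classes)))
    if len(condition_names) != spec.n_classes:
        raise ValueError("condition_names must match class_fractions")
    rng = np.random.default_rng(spec.seed)
    means = _class_means(spec)
    labels = rng.choice(spec.n_classes, size=spec.n_cells,
                        p=np.asarray(spec.class_fractions))
    out = []
    for j in labels:
        elong = float(np.clip(
            rng.normal(means[j], spec.class_spread * means[j]),
            spec.elongation_range[0] * 0.8, spec.elongation_range[1] * 1.2,
        ))
        n_prot = int(rng.integers(spec.protrusion_count_range[0],
                                  spec.protrusion_count_range[1] + 1))
        b = make_boundary(rng, elong, n_prot, spec.protrusion_amplitude,
                          spec.noise_sd, spec.base_radius_um)
        if spec.n_classes == 1:
            scalar_mean = 0.5
        else:
            scalar_mean = 0.25 + 0.5 * j / (spec.n_classes - 1)
        scalar = float(np.clip(rng.normal(scalar_mean, 0.1), 0.0, 1.0))
        out.append((b, condition_names[j], scalar))
    return out


# ---------------------------------------------------------------------------
# 3-D meshes
# ---------------------------------------------------------------------------

def make_mesh(
    rng: np.random.Generator,
    base_radius: float = 5.0,
    n_bumps: int = 4,
    bump_amplitude: float = 0.0,
    flatten_fraction: float = 0.35,
    tilt_deg: float = 0.0,
    noise_sd: float = 0.0,
    centroid_height: float | None = None,
    subdivisions: int = 3,
) -> trimesh.Trimesh:
    """One star-convex cell surface built from a displaced icosphere.

    Vertex radii are perturbed by smooth angular bumps (star-convexity is
    preserved while the perturbed radius stays positive), the bottom cap is
    clamped against a plane at z = -(1 - flatten_fraction) * base_radius to
    create a flat basal region whose facet normals are exactly (0, 0, -1),
    the mesh is optionally tilted about y, and finally translated so the
    volume centroid sits at ``centroid_height`` (if given).  With
    ``bump_amplitude = flatten_fraction = tilt_deg = noise_sd = 0`` and unit
    radius the output is exactly the unit icosphere.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = mesh.vertices.copy()
    r = np.full(len(v), float(base_radius))
    units = v  # icosphere vertices are unit vectors
    for _ in range(n_bumps):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        width = rng.uniform(0.25, 0.5)
        amp = bump_amplitude * rng.uniform(0.5, 1.0)
        ang = np.arccos(np.clip(units @ d, -1.0, 1.0))
        r = r + amp * np.exp(-0.5 * (ang / width) ** 2)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=len(v))
    r = np.maximum(r, 0.1 * base_radius)
    v = units * r[:, None]
    if flatten_fraction > 0:
        z_floor = -(1.0 - flatten_fraction) * base_radius
        v[:, 2] = np.maximum(v[:, 2], z_floor)
    mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
    if tilt_deg:
        mesh.apply_transform(trimesh.transformations.rotation_matrix(
            np.deg2rad(tilt_deg), [0, 1, 0]))
    if centroid_height is not None:
        mesh.apply_translation([0.0, 0.0,
                                centroid_height - mesh.center_mass[2]])
    return mesh


def make_mesh_population(
    spec: ShapePopulationSpec,
    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS_3D,
) -> list[tuple[trimesh.Trimesh, str, float]]:
    """Population of (mesh, condition label, centroid height um) triples.

    The first class emulates non-deformed monolayer cells (centroid height
    drawn in 4-8 um, no tilt); the second emulates photo-deformed cells
    (height 12-18 um, tilted 5-15 deg about y).  Heights are imposed exactly,
    so the 10 um labeling rule recovers the class by construction.
    """
    if spec.n_classes != 2:
        raise ValueError("mesh populations are two-class (non-deformed/deformed)")
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(2, size=spec.n_cells,
                        p=np.asarray(spec.class_fractions))
    out = []
    for j in labels:
        height = float(rng.uniform(4.0, 8.0) if j == 0
                       else rng.uniform(12.0, 18.0))
        tilt = 0.0 if j == 0 else float(rng.uniform(5.0, 15.0))
        elong = float(rng.uniform(*spec.elongation_range))
        mesh = make_mesh(
            rng,
            base_radius=spec.base_radius_um / 2.0,
            n_bumps=int(rng.integers(spec.protrusion_count_range[0],
                                     spec.protrusion_count_range[1] + 1)),
            bump_amplitude=spec.protrusion_amplitude / 2.0,
            flatten_fraction=0.35,
            tilt_deg=tilt,
            noise_sd=spec.noise_sd / 2.0,
            centroid_height=height,
        )
        # squash/stretch x to vary footprint elongation between cells
        mesh.vertices[:, 0] *= np.sqrt(elong)
        mesh.vertices[:, 1] /= np.sqrt(elong)
        mesh.apply_translation([0.0, 0.0, height - mesh.center_mass[2]])
        if not mesh.is_watertight:
            raise RuntimeError("generator produced a non-watertight mesh")
        assert label_deformation(height) == condition_names[j]
        out.append((mesh, condition_names[j], height))
    return out


# ---------------------------------------------------------------------------
# Fiber images
# ---------------------------------------------------------------------------

def make_fiber_image(spec: FiberImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Striped image + central disk mask; returns (image, mask).

    Intensity is offset + (contrast/2) * sin(2 pi (x sin a + y cos a) / T):
    at orientation a = 0 the image is constant along x and varies along y, and
    the (noise-free) gradient direction is (sin a, cos a) everywhere, so the
    dominant structure-tensor eigenvector lies at angle a from the y-varying
    axis.  The mask is a centered disk of radius 0.4 * min(width, height).
    """
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    phase = (xx * np.sin(spec.orientation) + yy * np.cos(spec.orientation))
    img = spec.contrast * (1.0 + np.sin(2.0 * np.pi * phase /
                                        spec.stripe_period)) / 2.0
    img = img + spec.contrast * 0.1  # positive floor
    if spec.background_noise_sd > 0:
        img = img + rng.normal(0.0, spec.background_noise_sd, size=img.shape)
    img = np.maximum(img, 0.0)
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.4 * min(spec.width,
                                                         spec.height)) ** 2
    return img, mask


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_population(out_dir, population, kind: str = "2d") -> "Path":
    """Write a generated population to disk in its interchange formats.

    2-D: one boundaries CSV plus a labels CSV; 3-D: one ASCII OBJ per cell
    plus a labels CSV.  Returns the labels CSV path.
    """
    import pandas as pd
    import tifffile  # noqa: F401  (re-exported convention; images use save_fiber_image)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    if kind == "2d":
        boundaries = {}
        for i, (b, label, scalar) in enumerate(population):
            cid = f"cell{i:04d}"
            boundaries[cid] = b
            rows.append({"cell_id": cid, "condition": label, "doa": scalar})
        write_boundaries_csv(out / "boundaries.csv", boundaries)
    elif kind == "3d":
        for i, (mesh, label, height) in enumerate(population):
            cid = f"cell{i:04d}"
            (out / f"{cid}.obj").write_text(
                trimesh.exchange.obj.export_obj(mesh))
            rows.append({"cell_id": cid, "condition": label,
                         "height_um": height})
    else:
        raise ValueError("kind must be '2d' or '3d'")
    labels_path = out / "labels.csv"
    pd.DataFrame(rows).to_csv(labels_path, index=False)
    return labels_path


def save_fiber_image(out_dir, img: np.ndarray, mask: np.ndarray,
                     stem: str = "fibers") -> tuple[Path, Path]:
    """Write the image as 16-bit TIFF and the mask as 8-bit PNG."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scaled = np.clip(img, 0, None)
    peak = scaled.max()
    if peak > 0:
        scaled = scaled / peak * 65535.0
    tif_path = out / f"{stem}.tif"
    tifffile.imwrite(tif_path, scaled.astype(np.uint16))
    png_path = out / f"{stem}_mask.png"
    Image.fromarray((mask.astype(np.uint8)) * 255).save(png_path)
    return tif_path, png_path
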