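"""Closed-contour alignment and truncated Fourier-series shape descriptors.

A cell (or nucleus) outline is an ordered, closed polygon in micrometres.
After pose normalization (centroid at the origin, first principal axis along
x, flips so most of the enclosed area lies in the first quadrant) the contour
is re-parameterized by normalized arc length theta in [0, 2*pi) and each
Cartesian coordinate is modeled as a truncated trigonometric series

    x(theta) = a0/2 + sum_n a_n cos(n theta) + b_n sin(n theta)
    y(theta) = c0/2 + sum_n c_n cos(n theta) + d_n sin(n theta)

solved by linear least squares.  With n harmonics each contour contributes
4*n + 2 coefficients (62 for the default cell-body order n=15, 22 for the
nucleus order n=5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

__all__ = [
    "Boundary2D",
    "FourierShape",
    "FitDiagnostics",
    "align_boundary",
    "arclength_parameterize",
    "fit_fourier",
    "reconstruct_fourier",
    "select_harmonics",
    "read_boundaries_csv",
    "write_boundaries_csv",
    "shapes_to_frame",
    "frame_to_shapes",
]

# Image resolution of the reference dataset; callers pass their own value.
DEFAULT_RESOLUTION_UM_PER_PX = 0.49
DEFAULT_N_SAMPLES = 360


@dataclass
class Boundary2D:
    """Ordered closed polygon (x, y) in micrometres; last point != first."""

    points: np.ndarray  # (N, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("boundary points must be an (N, 2) array")
        if len(self.points) < 8:
            raise ValueError("boundary needs at least 8 points")
        if np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
        if abs(self.signed_area()) < 1e-12:
            raise ValueError("boundary encloses zero area")

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area())

    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed polygon (not the vertex mean)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def counterclockwise(self) -> "Boundary2D":
        if self.signed_area() < 0:
            return Boundary2D(self.points[::-1].copy())
        return self


@dataclass
class FourierShape:
    """Coefficients of the truncated series for one closed contour."""

    n_harmonics: int
    a0: float
    c0: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_harmonics,):
                raise ValueError(
                    f"coefficient vector {name} must have length {self.n_harmonics}"
                )
            setattr(self, name, arr)

    @property
    def n_features(self) -> int:
        return 4 * self.n_harmonics + 2

    def flatten(self) -> np.ndarray:
        """Flatten to length 4n+2: a0, a_1..a_n, b_1..b_n, c0, c_1..c_n, d_1..d_n."""
        return np.concatenate([[self.a0], self.a, self.b, [self.c0], self.c, self.d])

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "FourierShape":
        flat = np.asarray(flat, dtype=float)
        if (len(flat) - 2) % 4:
            raise ValueError("flattened length must be 4n+2")
        n = (len(flat) - 2) // 4
        return cls(
            n_harmonics=n,
            a0=float(flat[0]),
            a=flat[1 : n + 1],
            b=flat[n + 1 : 2 * n + 1],
            c0=float(flat[2 * n + 1]),
            c=flat[2 * n + 2 : 3 * n + 2],
            d=flat[3 * n + 2 :],
        )

    def truncated(self, n_harmonics: int) -> "FourierShape":
        """Zero all harmonics above ``n_harmonics`` (keeps the feature layout)."""
        if n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        n = min(n_harmonics, self.n_harmonics)
        keep = np.zeros(self.n_harmonics)
        keep[:n] = 1.0
        return FourierShape(
            self.n_harmonics, self.a0, self.c0,
            self.a * keep, self.b * keep, self.c * keep, self.d * keep,
        )


@dataclass
class FitDiagnostics:
    rss: float
    aic: float
    bic: float
    n_params: int
    n_samples: int


# ---------------------------------------------------------------------------
# Pose normalization
# ---------------------------------------------------------------------------

def _first_quadrant_area(points: np.ndarray) -> float:
    poly = Polygon(points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    lim = float(np.abs(points).max()) * 2 + 1.0
    return poly.intersection(box(0.0, 0.0, lim, lim)).area


def align_boundary(b: Boundary2D, *, isotropy_rtol: float = 1e-9) -> Boundary2D:
    """Normalize pose: centroid to origin, principal axis to x, quadrant flip.

    The principal axis is the leading eigenvector of the boundary-point
    scatter.  Among the four axis-flip choices the one placing the largest
    enclosed area in the first quadrant is kept (ties keep the unflipped
    orientation).  Raises on zero-area input; for isotropic scatter the
    rotation falls back to the identity with a warning.
    """
    b = b.counterclockwise()
    pts = b.points - b.centroid()

    cov = np.cov(pts.T, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= isotropy_rtol * max(evals[1], 1e-300):
        warnings.warn(
            "isotropic point scatter: principal axis ill-defined, "
            "keeping original orientation",
            stacklevel=2,
        )
        rot = pts
    else:
        major = evecs[:, 1]  # eigh sorts ascending
        theta = np.arctan2(major[1], major[0])
        cs, sn = np.cos(-theta), np.sin(-theta)
        rot = pts @ np.array([[cs, -sn], [sn, cs]]).T

    best = None
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        cand = rot * np.array([sx, sy], dtype=float)
        score = _first_quadrant_area(cand)
        if best is None or score > best[0] + 1e-12:
            best = (score, cand)
    aligned = Boundary2D(best[1])
    # flips may reverse traversal; restore counterclockwise order
    aligned = aligned.counterclockwise()
    # re-center: rotation about the area centroid keeps it at the origin,
    # but guard against accumulation
    aligned = Boundary2D(aligned.points - aligned.centroid())
    return aligned


# ---------------------------------------------------------------------------
# Arc-length parameterization
# ---------------------------------------------------------------------------

def arclength_parameterize(
    b: Boundary2D, n_samples: int = DEFAULT_N_SAMPLES
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the contour at uniform normalized arc length.

    Returns ``(theta, xy)`` with ``theta[k] = 2 pi k / n_samples`` and
    ``xy[k]`` the point at cumulative arc length ``theta[k]/(2 pi) *
    perimeter``, traversed counterclockwise starting from the vertex with
    maximal x (ties broken toward larger y).
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    b = b.counterclockwise()
    pts = b.points
    # start vertex: max x, ties -> max y
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    start = order[-1]
    pts = np.roll(pts, -start, axis=0)

    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]

    theta = 2.0 * np.pi * np.arange(n_samples) / n_samples
    s = theta / (2.0 * np.pi) * perimeter
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return theta, np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Fourier fitting
# ---------------------------------------------------------------------------

def _design_matrix(theta: np.ndarray, n_harmonics: int) -> np.ndarray:
    n = np.arange(1, n_harmonics + 1)
    ang = np.outer(theta, n)
    return np.hstack([np.full((len(theta), 1), 0.5), np.cos(ang), np.sin(ang)])


def _information_criteria(rss: float, n_obs: int, n_params: int) -> tuple[float, float]:
    # Gaussian residual model: AIC = N ln(RSS/N) + 2p, BIC = N ln(RSS/N) + p ln N
    rss = max(rss, np.finfo(float).tiny)
    aic = n_obs * np.log(rss / n_obs) + 2 * n_params
    bic = n_obs * np.log(rss / n_obs) + n_params * np.log(n_obs)
    return float(aic), float(bic)


def fit_fourier(
    theta: np.ndarray, xy: np.ndarray, n_harmonics: int
) -> tuple[FourierShape, FitDiagnostics]:
    """Least-squares fit of the truncated series to arc-length samples.

    x and y are solved as two independent linear systems sharing one design
    matrix; diagnostics pool the residuals of both axes (N = 2 * n_samples,
    p = 4 n + 2).
    """
    theta = np.asarray(theta, dtype=float)
    xy = np.asarray(xy, dtype=float)
    n_samp = len(theta)
    n_params = 4 * n_harmonics + 2
    if 2 * n_samp < n_params:
        raise ValueError(
            f"underdetermined fit: {n_samp} samples for {n_harmonics} harmonics"
        )
    A = _design_matrix(theta, n_harmonics)
    coef, _, rank, _ = np.linalg.lstsq(A, xy, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix at n_harmonics={n_harmonics}"
        )
    resid = xy - A @ coef
    rss = float(np.sum(resid**2))
    aic, bic = _information_criteria(rss, 2 * n_samp, n_params)

    n = n_harmonics
    shape = FourierShape(
        n_harmonics=n,
        a0=float(coef[0, 0]),
        a=coef[1 : n + 1, 0].copy(),
        b=coef[n + 1 :, 0].copy(),
        c0=float(coef[0, 1]),
        c=coef[1 : n + 1, 1].copy(),
        d=coef[n + 1 :, 1].copy(),
    )
    diag = FitDiagnostics(rss, aic, bic, n_params, 2 * n_samp)
    return shape, diag


def evaluate_fourier(f: FourierShape, theta: np.ndarray) -> np.ndarray:
    """Evaluate the series at arbitrary theta; returns (len(theta), 2)."""
    A = _design_matrix(np.asarray(theta, dtype=float), f.n_harmonics)
    cx = np.concatenate([[f.a0], f.a, f.b])
    cy = np.concatenate([[f.c0], f.c, f.d])
    return np.column_stack([A @ cx, A @ cy])


def reconstruct_fourier(f: FourierShape, n_points: int = 256) -> Boundary2D:
    """Evaluate the series at uniform theta and return the closed contour."""
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    return Boundary2D(evaluate_fourier(f, theta))


def select_harmonics(
    b: Boundary2D, n_max: int, n_samples: int = DEFAULT_N_SAMPLES
) -> pd.DataFrame:
    """Fit at every order 1..n_max and tabulate (n, rss, aic, bic).

    The table is what the elbow criterion inspects: the order past which
    additional harmonics no longer noticeably reduce RSS/AIC/BIC.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    theta, xy = arclength_parameterize(b, n_samples)
    rows = []
    for n in range(1, n_max + 1):
        if 2 * n_samples < 4 * n + 2:
            warnings.warn(f"skipping underdetermined n={n}", stacklevel=2)
            continue
        _, diag = fit_fourier(theta, xy, n)
        rows.append({"n": n, "rss": diag.rss, "aic": diag.aic, "bic": diag.bic})
    return pd.DataFrame(rows)


def fit_boundary(
    b: Boundary2D,
    n_harmonics: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    align: bool = True,
) -> tuple[FourierShape, FitDiagnostics]:
    """Convenience pipeline: (align ->) parameterize -> fit."""
    if align:
        b = align_boundary(b)
    theta, xy = arclength_parameterize(b, n_samples)
    return fit_fourier(theta, xy, n_harmonics)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_boundaries_csv(path, boundaries: dict[str, Boundary2D]) -> None:
    """Write boundaries as tidy CSV: cell_id, point_index, x_um, y_um."""
    frames = []
    for cell_id, b in boundaries.items():
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "point_index": np.arange(len(b.points)),
                    "x_um": b.points[:, 0],
                    "y_um": b.points[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_boundaries_csv(path, resolution_um_per_px: float = 1.0) -> dict[str, Boundary2D]:
    """Read the tidy boundary CSV; optionally scale pixel coords to um."""
    df = pd.read_csv(path)
    out: dict[str, Boundary2D] = {}
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("point_index")
        pts = grp[["x_um", "y_um"]].to_numpy() * resolution_um_per_px
        out[str(cell_id)] = Boundary2D(pts)
    return out


def shapes_to_frame(shapes: dict[str, dict[str, FourierShape]]) -> pd.DataFrame:
    """Tabulate fitted shapes: cell_id, structure, n_harmonics, coefficients."""
    rows = []
    for cell_id, per_struct in shapes.items():
        for structure, f in per_struct.items():
            row = {"cell_id": cell_id, "structure": structure,
                   "n_harmonics": f.n_harmonics}
            n = f.n_harmonics
            row["a0"] = f.a0
            row.update({f"a{i+1}": f.a[i] for i in range(n)})
            row.update({f"b{i+1}": f.b[i] for i in range(n)})
            row["c0"] = f.c0
            row.update({f"c{i+1}": f.c[i] for i in range(n)})
            row.update({f"d{i+1}": f.d[i] for i in range(n)})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_shapes(df: pd.DataFrame) -> dict[str, dict[str, FourierShape]]:
    out: dict[str, dict[str, FourierShape]] = {}
    for _, row in df.iterrows():
        n = int(row["n_harmonics"])
        f = FourierShape(
            n_harmonics=n,
            a0=row["a0"],
            c0=row["c0"],
            a=np.array([row[f"a{i+1}"] for i in range(n)]),
            b=np.array([row[f"b{i+1}"] for i in range(n)]),
            c=np.array([row[f"c{i+1}"] for i in range(n)]),
            d=np.array([row[f"d{i+1}"] for i in range(n)]),
        )
        out.setdefault(str(row["cell_id"]), {})[str(row["structure"])] = f
    return out
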