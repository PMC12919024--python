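"""Outlier discovery in PC space and eigenshape interpretation.

Training records (one-hot columns stripped, features z-scored with the same
statistics as the generative pipeline) are eigendecomposed; the minimal K
components capturing at least 95% of the variance define the reduced space.
Each query cell's Mahalanobis distance from the training distribution is

    D_M(x) = sqrt( (x - mu)^T S^-1 (x - mu) )

which in PC coordinates reduces to sum_i (x_i - mu_i)^2 / lambda_i under the
root.  Cells with D_M^2 above the 95th-percentile chi-square quantile with K
degrees of freedom are flagged as statistical outliers; per-component
contributions (x_i - mu_i)^2 / lambda_i explain which shape modes drive the
flag, and sweeping a single component from -2 to +2 standard deviations
around the mean score, then inverting the PCA and the standardization, yields
the eigenshapes that visualize those modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .harmonize import NormalizationStats

__all__ = [
    "PCSpace",
    "build_pc_space",
    "project",
    "mahalanobis",
    "flag_outliers",
    "pc_contributions",
    "eigenshape",
]

VARIANCE_TARGET = 0.95
OUTLIER_QUANTILE = 0.95


@dataclass
class PCSpace:
    """PCA of standardized training features, truncated at >=95% variance."""

    stats: NormalizationStats  # standardization reused from harmonization
    mean_std: np.ndarray  # mean of the standardized training data (~0)
    eigenvectors: np.ndarray  # (n_features, K)
    eigenvalues: np.ndarray  # (K,) descending, positive
    mean_scores: np.ndarray  # training-mean PC scores (~0)
    K: int
    variance_target: float
    total_variance: float

    @property
    def explained_fraction(self) -> float:
        return float(self.eigenvalues.sum() / self.total_variance)


def _standardize(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (np.asarray(X, dtype=float) - stats.mean) / stats.sd


def build_pc_space(
    numeric: np.ndarray,
    stats: NormalizationStats | None = None,
    variance_target: float = VARIANCE_TARGET,
) -> PCSpace:
    """Eigendecompose the covariance of standardized training features.

    ``numeric`` holds raw numeric features (no one-hot columns).  If no
    standardization statistics are supplied they are fitted here (population
    sd); passing the harmonization stats guarantees the same scaling as the
    VAE pipeline.  K is the minimal component count whose cumulative
    explained variance reaches the target, capped at the matrix rank.
    """
    X = np.asarray(numeric, dtype=float)
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn("dropping zero-variance features", stacklevel=2)
        stats = NormalizationStats(
            columns=[f"f{i}" for i in np.nonzero(keep)[0]],
            mean=mean[keep], sd=sd[keep],
            excluded={f"f{i}": float(mean[i])
                      for i in np.nonzero(~keep)[0]},
        )
        X = X[:, keep]
    Z = _standardize(X, stats)
    mean_std = Z.mean(axis=0)
    cov = np.cov((Z - mean_std).T, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    total = float(evals.sum())
    cum = np.cumsum(evals) / total
    K = int(np.searchsorted(cum, variance_target) + 1)
    rank = int((evals > 1e-12 * max(evals[0], 1e-300)).sum())
    if K > rank:
        warnings.warn(
            f"variance target needs {K} components but rank is {rank}; "
            "capping K", stacklevel=2)
        K = rank
    evecs_k = evecs[:, :K]
    scores = (Z - mean_std) @ evecs_k
    return PCSpace(
        stats=stats, mean_std=mean_std, eigenvectors=evecs_k,
        eigenvalues=evals[:K], mean_scores=scores.mean(axis=0), K=K,
        variance_target=variance_target, total_variance=total,
    )


def project(space: PCSpace, numeric: np.ndarray) -> np.ndarray:
    """Project raw numeric feature rows into the retained PC space."""
    Z = _standardize(numeric, space.stats)
    return (Z - space.mean_std) @ space.eigenvectors


def mahalanobis(space: PCSpace, numeric: np.ndarray) -> np.ndarray:
    """Root Mahalanobis distance of each row from the training distribution.

    Computed in PC coordinates where the covariance is diagonal(lambda_i).
    Components with vanishing eigenvalue are excluded with a warning.
    """
    scores = project(space, numeric)
    lam = space.eigenvalues
    ok = lam > 1e-12 * max(float(lam[0]), 1e-300)
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} near-singular components from the "
            "distance", stacklevel=2)
    d2 = ((scores[:, ok] - space.mean_scores[ok]) ** 2 / lam[ok]).sum(axis=1)
    return np.sqrt(d2)


def flag_outliers(
    distances: np.ndarray, K: int,
    quantile: float = OUTLIER_QUANTILE,
    cell_ids=None,
) -> pd.DataFrame:
    """Chi-square outlier rule: D_M^2 > chi2_{q, K}.

    Returns a table with the distance, the (root) threshold and the flag.
    Under the null (query drawn from the training distribution) the rule
    flags a fraction 1 - q.
    """
    distances = np.asarray(distances, dtype=float)
    threshold = float(np.sqrt(chi2.ppf(quantile, df=K)))
    frame = pd.DataFrame({
        "mahalanobis": distances,
        "threshold": threshold,
        "is_outlier": distances > threshold,
    })
    if cell_ids is not None:
        frame.index = pd.Index(cell_ids, name="cell_id")
    return frame


def pc_contributions(space: PCSpace, numeric_row: np.ndarray
                     ) -> pd.DataFrame:
    """Per-component contributions (x_i - mu_i)^2 / lambda_i for one cell.

    Raw contributions sum to D_M^2; the normalized column sums to 1 and ranks
    the components (ties broken toward the lower PC index).
    """
    scores = project(space, np.atleast_2d(numeric_row))[0]
    raw = (scores - space.mean_scores) ** 2 / space.eigenvalues
    total = raw.sum()
    normed = raw / total if total > 0 else np.zeros_like(raw)
    frame = pd.DataFrame({
        "pc": np.arange(space.K),
        "contribution": raw,
        "normalized": normed,
    })
    return frame.sort_values(
        ["normalized", "pc"], ascending=[False, True]
    ).reset_index(drop=True)


def pc_density_plot(space: PCSpace, numeric: np.ndarray,
                    pc_pair: tuple[int, int] = (0, 1),
                    outliers: np.ndarray | None = None, ax=None):
    """2-D Gaussian-KDE density of training scores along two PCs.

    Optional visual companion to the outlier report: the training
    distribution is shaded along the chosen component pair and any outlier
    rows are overplotted as stars.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    i, j = pc_pair
    scores = project(space, numeric)[:, [i, j]]
    if ax is None:
        _, ax = plt.subplots()
    kde = gaussian_kde(scores.T)  # Silverman bandwidth
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    pad = 0.2 * (hi - lo + 1e-12)
    gx, gy = np.mgrid[lo[0] - pad[0]:hi[0] + pad[0]:100j,
                      lo[1] - pad[1]:hi[1] + pad[1]:100j]
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    ax.contourf(gx, gy, dens, levels=12, cmap="viridis")
    if outliers is not None and len(outliers):
        out_scores = project(space, np.atleast_2d(outliers))[:, [i, j]]
        ax.scatter(out_scores[:, 0], out_scores[:, 1], marker="*", s=120,
                   c="red", edgecolors="white", zorder=3, label="outlier")
        ax.legend()
    ax.set_xlabel(f"PC {i + 1}")
    ax.set_ylabel(f"PC {j + 1}")
    return ax


def invert_pc_scores(space: PCSpace, scores: np.ndarray) -> np.ndarray:
    """PC scores -> standardized features -> raw numeric feature rows."""
    Z = np.atleast_2d(scores) @ space.eigenvectors.T + space.mean_std
    return Z * space.stats.sd + space.stats.mean


def eigenshape(
    space: PCSpace,
    pc_index: int,
    decoder,
    sigma_steps=(-2.0, -1.0, 0.0, 1.0, 2.0),
) -> list:
    """Sweep one PC around the mean score and decode the resulting shapes.

    Starting from the training-mean score vector, the selected component is
    set to mean + step * sqrt(lambda) for each step, the scores are inverted
    through the PCA and the standardization, and ``decoder`` (a callable
    mapping one raw numeric feature row to a boundary or mesh) renders each
    feature vector.  All non-selected components stay at their training
    means.
    """
    if not (0 <= pc_index < space.K):
        raise IndexError(f"pc_index must be in [0, {space.K})")
    shapes = []
    sigma = np.sqrt(space.eigenvalues[pc_index])
    for step in sigma_steps:
        scores = space.mean_scores.copy()
        scores[pc_index] = space.mean_scores[pc_index] + step * sigma
        features = invert_pc_scores(space, scores)[0]
        shapes.append(decoder(features))
    return shapes
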