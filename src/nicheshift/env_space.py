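"""Environmental ordination (PCA-env) and kernel occupancy grids.

The two study regions' available climates (their "backgrounds") are
pooled, standardized to unit variance and reduced to two principal
components; occurrences and backgrounds are projected into this shared
plane.  Occurrence density is then estimated on an R x R grid spanning
the pooled-background extent with a Gaussian kernel (binned KDE:
2-D histogram followed by Gaussian smoothing, Silverman bandwidth per
axis), divided by the background density to correct for uneven climate
availability, and normalized to sum to one.  The corrected occupancy
``z`` is what the overlap statistic and the permutation tests consume;
the uncorrected density ``z_uncor`` is kept alongside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .occurrences import OccurrenceSet

__all__ = [
    "EnvPCA",
    "calibrate_env_space",
    "OccupancyGrid",
    "occupancy_grid",
    "background_masks",
    "mass_mask",
    "grid_extent",
    "silverman_bandwidth",
]


class EnvPCA(TransformerMixin, BaseEstimator):
    """Correlation-matrix PCA of pooled background environments.

    Variables are centered and scaled to unit variance before the
    decomposition (bioclim variables have incommensurate units), and
    component signs are fixed so each component's largest-magnitude
    loading is positive, making the ordination reproducible.

    Attributes (after ``fit``)
    --------------------------
    variable_names_ : list of retained variable names
    mean_, scale_ : per-variable standardization constants
    loadings_ : DataFrame (variables x [pc1, pc2]) of orthonormal loadings
    explained_variance_ratio_ : fractions of variance per component
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "EnvPCA":
        X = self._as_frame(X)
        scale = X.std(axis=0, ddof=0)
        dead = scale[scale == 0].index.tolist()
        if dead:
            warnings.warn(
                f"dropping zero-variance variables: {dead}", UserWarning, stacklevel=2
            )
            X = X.drop(columns=dead)
        if X.shape[1] < self.n_components:
            raise ValueError("fewer variables than requested components")
        if len(X.drop_duplicates()) < 3:
            raise ValueError("need at least 3 distinct background points")
        self.variable_names_ = list(X.columns)
        self.mean_ = X.mean(axis=0).to_numpy()
        self.scale_ = X.std(axis=0, ddof=0).to_numpy()
        Z = (X.to_numpy() - self.mean_) / self.scale_
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(Z)
        components = pca.components_.copy()  # (k, p)
        for k in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[k])))
            if components[k, j] < 0:
                components[k] = -components[k]
        self.components_ = components
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.loadings_ = pd.DataFrame(
            components.T,
            index=self.variable_names_,
            columns=[f"pc{i + 1}" for i in range(self.n_components)],
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = self._as_frame(X)
        missing = [v for v in self.variable_names_ if v not in X.columns]
        if missing:
            raise ValueError(f"input lacks variables {missing}")
        Z = (X[self.variable_names_].to_numpy() - self.mean_) / self.scale_
        return Z @ self.components_.T

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, OccurrenceSet):
            if X.env is None:
                raise ValueError("occurrence set has no environmental annotation")
            X = X.env
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"v{i}" for i in range(X.shape[1])]
        return X.astype(float)


def calibrate_env_space(
    background_native: pd.DataFrame,
    background_introduced: pd.DataFrame,
    n_components: int = 2,
) -> EnvPCA:
    """Fit the PCA-env on the pooled backgrounds of both regions."""
    for name, bg in (
        ("native", background_native),
        ("introduced", background_introduced),
    ):
        if bg is None or len(bg) == 0:
            raise ValueError(f"{name} background is empty")
    common = [c for c in background_native.columns if c in background_introduced.columns]
    if not common:
        raise ValueError("backgrounds share no variables")
    pooled = pd.concat(
        [background_native[common], background_introduced[common]], ignore_index=True
    )
    return EnvPCA(n_components=n_components).fit(pooled)


# ---------------------------------------------------------------- density grid
def silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Per-axis Silverman rule-of-thumb bandwidth for a 2-D point cloud."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("bandwidth undefined for fewer than 2 points")
    sd = points.std(axis=0, ddof=1)
    if np.any(sd == 0):
        sd = np.where(sd == 0, np.maximum(sd.max(), 1e-8), sd)
    return sd * n ** (-1.0 / 6.0)


def grid_extent(scores: np.ndarray, pad: float = 0.0) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of a score cloud, optionally padded."""
    scores = np.asarray(scores, dtype=float)
    xmin, ymin = scores.min(axis=0)
    xmax, ymax = scores.max(axis=0)
    dx = (xmax - xmin) or 1.0
    dy = (ymax - ymin) or 1.0
    return (xmin - pad * dx, xmax + pad * dx, ymin - pad * dy, ymax + pad * dy)


def raw_histogram(
    scores: np.ndarray, extent: tuple[float, float, float, float], R: int
) -> np.ndarray:
    """R x R count histogram of a 2-D score cloud over ``extent``."""
    scores = np.asarray(scores, dtype=float)
    xmin, xmax, ymin, ymax = extent
    hist, _, _ = np.histogram2d(
        scores[:, 0],
        scores[:, 1],
        bins=R,
        range=[[xmin, xmax], [ymin, ymax]],
    )
    return hist


def smooth_density(
    hist: np.ndarray,
    bandwidth: Sequence[float],
    extent: tuple[float, float, float, float],
    R: int,
) -> np.ndarray:
    """Gaussian-smooth a count histogram and normalize it to sum 1.

    Mass smoothed past the grid border is truncated before
    renormalization.
    """
    xmin, xmax, ymin, ymax = extent
    cell = np.array([(xmax - xmin) / R, (ymax - ymin) / R])
    sigma_cells = np.asarray(bandwidth, dtype=float) / cell
    out = np.asarray(hist, dtype=float)
    if np.any(sigma_cells > 0):
        out = gaussian_filter(out, sigma=sigma_cells, mode="constant", cval=0.0)
    total = out.sum()
    if total <= 0:
        raise ValueError("no density mass on the grid (all points outside extent?)")
    return out / total


def density_on_grid(
    scores: np.ndarray,
    extent: tuple[float, float, float, float],
    R: int = 100,
    bandwidth: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Binned Gaussian-kernel density on an R x R grid, normalized to sum 1.

    Points are histogrammed onto the grid and smoothed with a Gaussian
    kernel whose per-axis bandwidth (in score units) defaults to
    Silverman's rule on the points being smoothed.
    """
    scores = np.asarray(scores, dtype=float)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(scores)
    return smooth_density(raw_histogram(scores, extent, R), bandwidth, extent, R)


@dataclass
class OccupancyGrid:
    """Kernel-smoothed occupancy of one range in the shared PCA plane.

    ``z`` is the background-corrected occupancy (occurrence density over
    background density, normalized to sum 1), ``z_uncor`` the normalized
    occurrence density alone, and ``e`` the background density.  The
    boolean masks delineate the cells holding 100 % and 75 % of the
    background environmental density.
    """

    z: np.ndarray
    z_uncor: np.ndarray
    e: np.ndarray
    extent: tuple[float, float, float, float]
    R: int
    mask_100: np.ndarray
    mask_75: np.ndarray
    bandwidth: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z", "z_uncor", "e"):
            a = getattr(self, name)
            if a.shape != (self.R, self.R):
                raise ValueError(f"{name} is not an {self.R}x{self.R} grid")
            if np.any(a < 0):
                raise ValueError(f"{name} has negative entries")
        for name in ("z", "z_uncor"):
            if abs(getattr(self, name).sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
        if np.any(self.mask_75 & ~self.mask_100):
            raise ValueError("mask_75 is not nested within mask_100")

    def mask_at(self, level: float) -> np.ndarray:
        if np.isclose(level, 1.0):
            return self.mask_100
        if np.isclose(level, 0.75):
            return self.mask_75
        return mass_mask(self.e, level)

    def occupancy(self, corrected: bool = True) -> np.ndarray:
        return self.z if corrected else self.z_uncor


def mass_mask(e: np.ndarray, level: float) -> np.ndarray:
    """Smallest cell set holding ``level`` of the total density mass.

    Cells are ranked by density descending; the mask marks the leading
    cells whose cumulative mass first reaches ``level`` of the total.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("density must be non-negative")
    total = e.sum()
    if total <= 0:
        raise ValueError("density is identically zero")
    flat = e.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    target = level * total - 1e-12 * total
    k = int(np.searchsorted(csum, target)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(e.shape)


def background_masks(
    e: np.ndarray, levels: Sequence[float] = (1.0, 0.75)
) -> tuple[np.ndarray, ...]:
    """Masks of the cells holding the given background-density quantiles."""
    return tuple(mass_mask(e, q) for q in levels)


def occupancy_grid(
    space: EnvPCA,
    occ: OccurrenceSet,
    background: pd.DataFrame,
    R: int = 100,
    extent: Optional[tuple[float, float, float, float]] = None,
    bandwidth: Optional[Sequence[float]] = None,
) -> OccupancyGrid:
    """Project a range's occurrences and background and grid its occupancy.

    ``extent`` should span the pooled backgrounds of both compared
    regions so that two ranges' grids are commensurable; it defaults to
    this range's own background extent.
    """
    if R < 10:
        raise ValueError("grid resolution R must be at least 10")
    if occ.env is None or len(occ) == 0:
        raise ValueError("occurrence set is empty or not annotated")
    if len(occ) < 2:
        raise ValueError("bandwidth undefined for a single occurrence")
    if background is None or len(background) == 0:
        raise ValueError("background table is empty")
    s_occ = space.transform(occ)
    s_bg = space.transform(background)
    if extent is None:
        extent = grid_extent(s_bg)
    bg_hist = raw_histogram(s_bg, extent, R)
    return occupancy_from_scores(s_occ, bg_hist, extent, R, bandwidth=bandwidth)


def occupancy_from_scores(
    scores: np.ndarray,
    bg_hist: np.ndarray,
    extent: tuple[float, float, float, float],
    R: int = 100,
    bandwidth: Optional[Sequence[float]] = None,
) -> OccupancyGrid:
    """Occupancy grid from precomputed PCA scores and a background histogram.

    The availability correction is a kernel density *ratio*: the
    occurrence density ``o`` and the background density ``e`` are both
    smoothed with the same (occurrence Silverman) bandwidth, which keeps
    the ratio stable at the climate margin where both densities decay
    and makes the occupancy exactly invariant to duplicating the
    background table.  The permutation tests call this directly,
    re-smoothing permuted occurrence pools against a fixed background
    histogram.
    """
    scores = np.asarray(scores, dtype=float)
    if bandwidth is not None:
        bw = np.asarray(bandwidth, dtype=float)
    else:
        # floor at one grid cell so degenerate point clouds still smooth
        xmin, xmax, ymin, ymax = extent
        cell = np.array([(xmax - xmin) / R, (ymax - ymin) / R])
        bw = np.maximum(silverman_bandwidth(scores), cell)
    o = smooth_density(raw_histogram(scores, extent, R), bw, extent, R)
    e = smooth_density(bg_hist, bw, extent, R)
    support = e > 0  # z vanishes off the background
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(support, o / np.where(support, e, 1.0), 0.0)
    total = ratio.sum()
    if total <= 0:
        raise ValueError("occurrence density lies entirely outside the background")
    z = ratio / total
    mask_100, mask_75 = background_masks(e)
    return OccupancyGrid(
        z=z,
        z_uncor=o,
        e=e,
        extent=tuple(extent),
        R=R,
        mask_100=mask_100,
        mask_75=mask_75,
        bandwidth=bw,
    )
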