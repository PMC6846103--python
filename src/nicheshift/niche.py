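"""Niche overlap, niche dynamics and permutation tests.

Overlap between two ranges' occupancies ``z1, z2`` (normalized to sum
one on a shared environmental grid) is Schoener's

    D = 1 - (1/2) * sum |z1 - z2|,

0 for disjoint niches and 1 for identical ones.  The niche dynamics
indices decompose an invasion within analogous climates (cells covering
a stated quantile of both backgrounds): *expansion* is the fraction of
introduced occupancy outside the native niche, *stability* its
complement, and *unfilling* the fraction of native occupancy outside
the introduced niche.  Because kernel-smoothed densities are never
exactly zero inside the smoothing radius, a range's "niche" is
operationalised as the smallest cell set holding ``support_mass``
(default 99 %) of its occupancy; discrete toy grids retain their exact
zero/non-zero behaviour under this rule.

Two permutation tests accompany the overlap value.  The *equivalence*
test pools both ranges' occurrences and reallocates them at random
(group sizes fixed), rebuilding both occupancy grids and recomputing D
each iteration; equivalence is rejected when the observed D falls in
the low tail of the null.  The *similarity* test relocates one range's
whole occupancy to a uniformly random position inside that range's
background and asks whether the observed overlap exceeds chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .env_space import (
    EnvPCA,
    OccupancyGrid,
    grid_extent,
    mass_mask,
    occupancy_from_scores,
    raw_histogram,
)
from .occurrences import OccurrenceSet

GridLike = Union[OccupancyGrid, np.ndarray]

__all__ = [
    "NicheComparison",
    "PermutationResult",
    "schoener_d",
    "support_mask",
    "niche_dynamics",
    "equivalence_test",
    "similarity_test",
]


@dataclass
class NicheComparison:
    """Overlap plus dynamics indices for a native/introduced pair."""

    D: float
    stability: float
    expansion: float
    unfilling: float
    analog_level: float

    def __post_init__(self) -> None:
        if not (0 <= self.D <= 1):
            raise ValueError("D must lie in [0, 1]")
        if abs(self.expansion + self.stability - 1.0) > 1e-9:
            raise ValueError("expansion + stability must equal 1")
        if not (0 <= self.unfilling <= 1):
            raise ValueError("unfilling must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "stability": self.stability,
            "expansion": self.expansion,
            "unfilling": self.unfilling,
            "analog_level": self.analog_level,
        }


@dataclass
class PermutationResult:
    """Observed overlap, its permutation null and the one-tailed p-value."""

    D_obs: float
    D_null: np.ndarray
    n_iter: int
    p_value: float
    test: str
    direction: str

    def to_dict(self) -> dict:
        return {
            "D_obs": self.D_obs,
            "n_iter": self.n_iter,
            "p_value": self.p_value,
            "test": self.test,
            "direction": self.direction,
            "D_null_mean": float(np.mean(self.D_null)),
            "D_null_sd": float(np.std(self.D_null)),
        }


def _as_z(grid: GridLike, corrected: bool) -> np.ndarray:
    if isinstance(grid, OccupancyGrid):
        return grid.occupancy(corrected)
    z = np.asarray(grid, dtype=float)
    if np.any(z < 0):
        raise ValueError("occupancy must be non-negative")
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy is identically zero")
    return z / total


def _check_commensurable(a: GridLike, b: GridLike) -> None:
    if isinstance(a, OccupancyGrid) and isinstance(b, OccupancyGrid):
        if a.R != b.R or not np.allclose(a.extent, b.extent):
            raise ValueError("occupancy grids do not share extent and resolution")
    za = a.z if isinstance(a, OccupancyGrid) else np.asarray(a)
    zb = b.z if isinstance(b, OccupancyGrid) else np.asarray(b)
    if za.shape != zb.shape:
        raise ValueError(f"grid shapes differ: {za.shape} vs {zb.shape}")


def schoener_d(z1: GridLike, z2: GridLike, corrected: bool = True) -> float:
    """Schoener's D overlap between two normalized occupancy grids."""
    _check_commensurable(z1, z2)
    a = _as_z(z1, corrected)
    b = _as_z(z2, corrected)
    return float(np.clip(1.0 - 0.5 * np.abs(a - b).sum(), 0.0, 1.0))


def support_mask(z: np.ndarray, mass: float = 0.99) -> np.ndarray:
    """Cells holding the top ``mass`` fraction of occupancy (the niche)."""
    return mass_mask(z, mass)


def niche_dynamics(
    z_native: GridLike,
    z_introduced: GridLike,
    analog_level: float = 1.0,
    support_mass: float = 0.99,
    corrected: bool = True,
) -> NicheComparison:
    """Expansion / stability / unfilling within analogous climates.

    ``analog_level`` restricts the comparison to cells covering that
    quantile of *both* backgrounds (1.0 or 0.75 conventionally); plain
    arrays carry no background, so the full grid is used.
    """
    _check_commensurable(z_native, z_introduced)
    zn = _as_z(z_native, corrected)
    zi = _as_z(z_introduced, corrected)
    if isinstance(z_native, OccupancyGrid) and isinstance(z_introduced, OccupancyGrid):
        analog = z_native.mask_at(analog_level) & z_introduced.mask_at(analog_level)
    else:
        analog = np.ones(zn.shape, dtype=bool)
    if not analog.any():
        raise ValueError("no analogous climate: analog masks do not intersect")
    zn_m = np.where(analog, zn, 0.0)
    zi_m = np.where(analog, zi, 0.0)
    if zn_m.sum() <= 0 or zi_m.sum() <= 0:
        raise ValueError("no occupancy mass within the analogous climate")
    zn_m /= zn_m.sum()
    zi_m /= zi_m.sum()
    native_niche = support_mask(zn_m, support_mass)
    introduced_niche = support_mask(zi_m, support_mass)
    expansion = float(zi_m[~native_niche].sum())
    unfilling = float(zn_m[~introduced_niche].sum())
    expansion = min(max(expansion, 0.0), 1.0)
    unfilling = min(max(unfilling, 0.0), 1.0)
    return NicheComparison(
        D=schoener_d(zn, zi),
        stability=1.0 - expansion,
        expansion=expansion,
        unfilling=unfilling,
        analog_level=analog_level,
    )


# ------------------------------------------------------------------ tests
def _perm_p(null: np.ndarray, obs: float, direction: str) -> float:
    n = len(null)
    if direction == "lower":
        extreme = int(np.sum(null <= obs + 1e-12))
    elif direction == "higher":
        extreme = int(np.sum(null >= obs - 1e-12))
    else:
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    return (extreme + 1) / (n + 1)


def _prepare_pair(space, occ1, occ2, background1, background2, R):
    s1 = space.transform(occ1)
    s2 = space.transform(occ2)
    b1 = space.transform(background1)
    b2 = space.transform(background2)
    extent = grid_extent(np.vstack([b1, b2]))
    bh1 = raw_histogram(b1, extent, R)
    bh2 = raw_histogram(b2, extent, R)
    return s1, s2, bh1, bh2, extent


def equivalence_test(
    occ1: OccurrenceSet,
    occ2: OccurrenceSet,
    space: EnvPCA,
    background1: pd.DataFrame,
    background2: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | Sequence[int] = 0,
    R: int = 100,
    corrected: bool = True,
    direction: str = "lower",
) -> PermutationResult:
    """Niche equivalence permutation test.

    Pools the occurrences of both ranges and, at each iteration,
    reallocates them at random into two groups of the observed sizes,
    rebuilds both occupancy grids (each against its own background) and
    recomputes D.  With ``direction='lower'`` equivalence is rejected
    when the observed D is in the low 5 % of the null.
    """
    if n_iter < 99:
        raise ValueError("n_iter must be at least 99")
    n1, n2 = len(occ1), len(occ2)
    if min(n1, n2) < 5:
        warnings.warn(
            "group with fewer than 5 occurrences: kernel estimates are unstable",
            UserWarning,
            stacklevel=2,
        )
    s1, s2, bh1, bh2, extent = _prepare_pair(
        space, occ1, occ2, background1, background2, R
    )
    z1 = occupancy_from_scores(s1, bh1, extent, R)
    z2 = occupancy_from_scores(s2, bh2, extent, R)
    D_obs = schoener_d(z1, z2, corrected)
    pooled = np.vstack([s1, s2])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(n1 + n2)
        g1 = pooled[perm[:n1]]
        g2 = pooled[perm[n1:]]
        try:
            zz1 = occupancy_from_scores(g1, bh1, extent, R)
            zz2 = occupancy_from_scores(g2, bh2, extent, R)
        except ValueError:
            # a permuted group with no mass on its background has no
            # measurable overlap
            null[i] = 0.0
            continue
        null[i] = schoener_d(zz1, zz2, corrected)
    return PermutationResult(
        D_obs=D_obs,
        D_null=null,
        n_iter=n_iter,
        p_value=_perm_p(null, D_obs, direction),
        test="equivalence",
        direction=direction,
    )


def _shift_grid(z: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a grid by whole cells, dropping mass shifted off-grid."""
    out = np.zeros_like(z)
    R, C = z.shape
    r0, r1 = max(0, dr), min(R, R + dr)
    c0, c1 = max(0, dc), min(C, C + dc)
    out[r0:r1, c0:c1] = z[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def similarity_test(
    occ_focal: OccurrenceSet,
    occ_other: OccurrenceSet,
    space: EnvPCA,
    background_focal: pd.DataFrame,
    background_other: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | Sequence[int] = 0,
    R: int = 100,
    corrected: bool = True,
    direction: str = "higher",
) -> PermutationResult:
    """Niche similarity permutation test.

    The null translates the other range's whole occupancy (shape
    preserved) to a uniformly random location within that range's
    background and recomputes D against the focal occupancy.  With
    ``direction='higher'`` similarity beyond chance is supported when
    the observed D exceeds nearly all null values.
    """
    if n_iter < 99:
        raise ValueError("n_iter must be at least 99")
    s_f, s_o, bh_f, bh_o, extent = _prepare_pair(
        space, occ_focal, occ_other, background_focal, background_other, R
    )
    z_f = occupancy_from_scores(s_f, bh_f, extent, R)
    z_o = occupancy_from_scores(s_o, bh_o, extent, R)
    zf = z_f.occupancy(corrected)
    zo = z_o.occupancy(corrected)
    D_obs = float(np.clip(1.0 - 0.5 * np.abs(zf - zo).sum(), 0.0, 1.0))
    bg_mask = mass_mask(z_o.e, 1.0)
    candidates = np.argwhere(bg_mask)
    if len(candidates) < 2:
        raise ValueError("background too small to relocate the niche")
    com = ndimage.center_of_mass(zo)
    center = np.array([int(round(com[0])), int(round(com[1]))])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    picks = candidates[rng.integers(0, len(candidates), size=n_iter)]
    for i in range(n_iter):
        dr, dc = picks[i] - center
        shifted = _shift_grid(zo, int(dr), int(dc))
        total = shifted.sum()
        if total <= 0:
            null[i] = 0.0
            continue
        shifted = shifted / total
        null[i] = float(np.clip(1.0 - 0.5 * np.abs(zf - shifted).sum(), 0.0, 1.0))
    return PermutationResult(
        D_obs=D_obs,
        D_null=null,
        n_iter=n_iter,
        p_value=_perm_p(null, D_obs, direction),
        test="similarity",
        direction=direction,
    )
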