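"""Optional diagnostic plots (niche in PCA space, permutation nulls,
variable importances)."""

from __future__ import annotations

import numpy as np

from .env_space import OccupancyGrid
from .niche import PermutationResult


def plot_niche(
    z_native: OccupancyGrid,
    z_introduced: OccupancyGrid,
    ax=None,
    support_mass: float = 0.99,
):
    """Occupancy of both ranges in the shared PCA plane.

    Stable cells (both niches) in blue, expansion (introduced only) in
    red, unfilling (native only) in green; background mass contours at
    100 % (solid) and 75 % (dashed).
    """
    import matplotlib.pyplot as plt
    from .niche import support_mask

    if ax is None:
        _, ax = plt.subplots()
    xmin, xmax, ymin, ymax = z_native.extent
    nat = support_mask(z_native.z, support_mass)
    intr = support_mask(z_introduced.z, support_mass)
    rgb = np.ones(nat.shape + (3,))
    rgb[nat & intr] = (0.55, 0.65, 0.95)   # stability
    rgb[intr & ~nat] = (0.95, 0.55, 0.55)  # expansion
    rgb[nat & ~intr] = (0.55, 0.85, 0.55)  # unfilling
    ax.imshow(
        np.transpose(rgb, (1, 0, 2)),
        origin="lower",
        extent=(xmin, xmax, ymin, ymax),
        aspect="auto",
    )
    for grid, style in ((z_native, "-"), (z_introduced, "--")):
        ax.contour(
            grid.e.T > 0,
            levels=[0.5],
            colors="k",
            linestyles=style,
            extent=(xmin, xmax, ymin, ymax),
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax


def plot_null_distribution(result: PermutationResult, ax=None):
    """Histogram of the permutation null with the observed D marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(result.D_null, bins=30, color="0.7", edgecolor="0.4")
    ax.axvline(result.D_obs, color="crimson", lw=2)
    ax.set_xlabel("Schoener's D")
    ax.set_ylabel("count")
    ax.set_title(f"{result.test} test: D = {result.D_obs:.3f}, p = {result.p_value:.3f}")
    return ax


def plot_importance(importance, ax=None, title: str = ""):
    """Horizontal bar plot of variable importances (largest at top)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    imp = importance.sort_values()
    ax.barh(imp.index.astype(str), imp.to_numpy(), color="0.5")
    ax.set_xlabel("permutation importance")
    if title:
        ax.set_title(title)
    return ax
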