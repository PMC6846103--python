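"""Occurrence-density performance along a climate axis and its link to
leaf physiology.

*Performance* is a range's relative occurrence density across bins of a
bioclimatic variable (default bio11, mean temperature of the coldest
quarter), interpolated at the experiment's sampling temperatures; it is
a distribution-side proxy for how well a range does at a given winter
temperature.  Random-forest models then (a) classify range membership
from the physiological markers and (b) regress performance on them,
reporting permutation variable importance and out-of-bag explained
variance -- the machinery linking chilling physiology to invasion
dynamics.

Two exact marker formulas live here as well: the xanthophyll
de-epoxidation state DPS = (Zx + Ax) / (Vx + Ax + Zx) and leaf
hydration H = (FW - DW) / DW.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance

from .grids import ClimateGrid
from .occurrences import OccurrenceSet, extract_env
from .synthetic import EXPERIMENT1_TEMPERATURES

__all__ = [
    "dps",
    "leaf_hydration",
    "PerformanceTable",
    "performance_curve",
    "LinkModelResult",
    "link_classification",
    "link_regression",
]


def dps(Zx, Ax, Vx):
    """Xanthophyll de-epoxidation state (Zx + Ax) / (Vx + Ax + Zx).

    All pigment contents must be non-negative with a non-empty pool;
    returns a value in [0, 1] (1 when fully de-epoxidated, i.e. Vx = 0).
    """
    Zx, Ax, Vx = (np.asarray(v, dtype=float) for v in (Zx, Ax, Vx))
    if np.any(Zx < 0) or np.any(Ax < 0) or np.any(Vx < 0):
        raise ValueError("pigment contents must be non-negative")
    pool = Zx + Ax + Vx
    if np.any(pool <= 0):
        raise ValueError("xanthophyll pool (Vx + Ax + Zx) must be positive")
    out = (Zx + Ax) / pool
    return float(out) if out.ndim == 0 else out


def leaf_hydration(FW, DW):
    """Leaf water content (FW - DW) / DW, in g water per g dry weight."""
    FW, DW = np.asarray(FW, dtype=float), np.asarray(DW, dtype=float)
    if np.any(DW <= 0):
        raise ValueError("dry weight must be positive")
    if np.any(FW < DW):
        raise ValueError("fresh weight cannot be below dry weight")
    out = (FW - DW) / DW
    return float(out) if out.ndim == 0 else out


@dataclass
class PerformanceTable:
    """Per-range relative occurrence density over bins of a climate variable.

    ``density[range]`` sums to one; ``performance`` holds the density
    linearly interpolated at the experimental temperatures, zero (and
    flagged) where a temperature falls outside that range's observed
    climate span.
    """

    variable: str
    bin_edges: np.ndarray
    density: Dict[str, np.ndarray]
    spans: Dict[str, tuple[float, float]]
    performance: pd.DataFrame

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def performance_at(
        self, range_label: str, temperature: float, join: str = "interpolate"
    ) -> float:
        """Relative density of a range at a temperature.

        ``join='interpolate'`` interpolates linearly between bin centers
        (clamping at the outer centers); ``join='nearest'`` returns the
        nearest bin's density.  Outside the range's observed span the
        performance is 0.
        """
        if range_label not in self.density:
            raise KeyError(f"no density for range {range_label!r}")
        lo, hi = self.spans[range_label]
        if temperature < lo or temperature > hi:
            return 0.0
        centers = self.bin_centers
        d = self.density[range_label]
        if join == "nearest":
            return float(d[int(np.argmin(np.abs(centers - temperature)))])
        if join != "interpolate":
            raise ValueError(f"unknown join mode {join!r}")
        return float(np.interp(temperature, centers, d))


def performance_curve(
    occ: OccurrenceSet,
    grid: Optional[ClimateGrid] = None,
    variable: str = "bio11",
    bins: int = 20,
    temperatures: Sequence[float] = EXPERIMENT1_TEMPERATURES,
) -> PerformanceTable:
    """Bin each range's occurrences along a climate variable.

    Equal-width bins span the pooled values of all ranges; each range's
    histogram is normalized to sum one.  The performance at each
    experimental temperature is interpolated between bin centers and
    flagged as extrapolated (performance 0) where the temperature lies
    outside that range's observed span.
    """
    if occ.env is None:
        if grid is None:
            raise ValueError("occurrences are not annotated and no grid was given")
        occ = extract_env(occ, grid)
    if variable not in occ.env.columns:
        raise ValueError(f"variable {variable!r} not among the annotated layers")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    values = occ.env[variable].to_numpy(dtype=float)
    edges = np.histogram_bin_edges(values, bins=bins)
    density: Dict[str, np.ndarray] = {}
    spans: Dict[str, tuple[float, float]] = {}
    for label in occ.ranges:
        v = values[(occ.data["range"] == label).to_numpy()]
        if v.size == 0:
            continue
        counts, _ = np.histogram(v, bins=edges)
        density[label] = counts / counts.sum()
        spans[label] = (float(v.min()), float(v.max()))
    table = PerformanceTable(
        variable=variable,
        bin_edges=edges,
        density=density,
        spans=spans,
        performance=pd.DataFrame(),
    )
    rows = []
    for label in density:
        lo, hi = spans[label]
        for t in temperatures:
            outside = t < lo or t > hi
            rows.append(
                {
                    "range": label,
                    "temperature": float(t),
                    "performance": table.performance_at(label, float(t)),
                    "extrapolated": bool(outside),
                }
            )
    table.performance = pd.DataFrame(rows)
    return table


@dataclass
class LinkModelResult:
    """Random-forest link-model summary."""

    mode: str  # "classification" | "regression"
    variable_importance: pd.Series
    importance_by_range: Dict[str, pd.Series] = field(default_factory=dict)
    oob_error: Optional[float] = None
    explained_variance_pct: Optional[float] = None
    model: object = None

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "variable_importance": {
                k: float(v) for k, v in self.variable_importance.items()
            },
        }
        if self.oob_error is not None:
            out["oob_error"] = float(self.oob_error)
        if self.explained_variance_pct is not None:
            out["explained_variance_pct"] = float(self.explained_variance_pct)
        if self.importance_by_range:
            out["importance_by_range"] = {
                r: {k: float(v) for k, v in s.items()}
                for r, s in self.importance_by_range.items()
            }
        return out


def _wide_markers(markers: pd.DataFrame) -> pd.DataFrame:
    required = {"plant", "range", "temperature", "variable", "value"}
    missing = required - set(markers.columns)
    if missing:
        raise ValueError(f"marker table lacks columns {sorted(missing)}")
    wide = markers.pivot_table(
        index=["plant", "range", "temperature"],
        columns="variable",
        values="value",
        aggfunc="mean",
    )
    return wide.reset_index()


def link_classification(
    markers: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 1000,
    n_permutations: int = 10,
) -> LinkModelResult:
    """Random-forest classification of range membership from markers.

    Reports overall and per-range permutation variable importance and
    the out-of-bag error.
    """
    wide = _wide_markers(markers)
    feature_cols = [c for c in wide.columns if c not in ("plant", "range", "temperature")]
    X = wide[feature_cols]
    y = wide["range"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two range labels to classify")
    if counts.min() < 2:
        raise ValueError("need at least 2 plants per range")
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    overall = permutation_importance(
        rf, X, y, n_repeats=n_permutations, random_state=seed
    )
    importance = pd.Series(overall.importances_mean, index=feature_cols).sort_values(
        ascending=False
    )
    by_range: Dict[str, pd.Series] = {}
    for label in classes:
        sub = (y == label)
        res = permutation_importance(
            rf, X.loc[sub], y[sub], n_repeats=n_permutations, random_state=seed
        )
        by_range[str(label)] = pd.Series(
            res.importances_mean, index=feature_cols
        ).sort_values(ascending=False)
    return LinkModelResult(
        mode="classification",
        variable_importance=importance,
        importance_by_range=by_range,
        oob_error=float(1.0 - rf.oob_score_),
        model=rf,
    )


def link_regression(
    markers: pd.DataFrame,
    perf: PerformanceTable,
    range_label: str,
    seed: int = 0,
    n_trees: int = 1000,
    n_permutations: int = 10,
    join: str = "interpolate",
) -> LinkModelResult:
    """Random-forest regression of performance on the markers of one range.

    Each plant x temperature marker profile is joined to the range's
    performance at that temperature; the model reports out-of-bag
    explained variance (percent, may be negative when markers carry no
    signal) and permutation variable importance.
    """
    wide = _wide_markers(markers)
    wide = wide[wide["range"] == range_label]
    if wide.empty:
        raise ValueError(f"no marker rows for range {range_label!r}")
    temps = wide["temperature"].unique()
    if len(temps) < 3:
        raise ValueError("performance response undefined: fewer than 3 temperatures")
    feature_cols = [c for c in wide.columns if c not in ("plant", "range", "temperature")]
    X = wide[feature_cols]
    y = np.array(
        [
            perf.performance_at(range_label, float(t), join=join)
            for t in wide["temperature"]
        ]
    )
    rf = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    res = permutation_importance(rf, X, y, n_repeats=n_permutations, random_state=seed)
    importance = pd.Series(res.importances_mean, index=feature_cols).sort_values(
        ascending=False
    )
    return LinkModelResult(
        mode="regression",
        variable_importance=importance,
        explained_variance_pct=float(100.0 * rf.oob_score_),
        model=rf,
    )
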