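"""Presence-record handling: loading, validation, spatial thinning and
environmental annotation.

Mirrors the record-filtering protocol of range-comparison studies built
on aggregated presence-only archives: drop records with unusable
coordinates, remove near-duplicates within a minimum geographic
distance (default 1 km), then annotate every retained record with the
value of each climate layer at its containing raster cell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import ClimateGrid

EARTH_RADIUS_KM = 6371.0

_LON_ALIASES = ("lon", "long", "longitude", "decimallongitude", "x")
_LAT_ALIASES = ("lat", "latitude", "decimallatitude", "y")

__all__ = [
    "OccurrenceSet",
    "load_occurrences",
    "thin_occurrences",
    "extract_env",
    "haversine_km",
]


@dataclass
class OccurrenceSet:
    """Presence records for one or more range labels.

    ``data`` holds one row per record with at least ``lon``, ``lat`` and
    ``range`` columns; ``env`` (when annotated) is row-aligned with
    ``data`` and holds one column per environmental variable.  ``report``
    accumulates counts from cleaning steps.
    """

    data: pd.DataFrame
    env: Optional[pd.DataFrame] = None
    provenance: str = ""
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("lon", "lat", "range"):
            if col not in self.data.columns:
                raise ValueError(f"occurrence data lacks required column {col!r}")
        if self.env is not None and len(self.env) != len(self.data):
            raise ValueError("env table is not row-aligned with the records")
        self.data = self.data.reset_index(drop=True)
        if self.env is not None:
            self.env = self.env.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ranges(self) -> list[str]:
        return list(pd.unique(self.data["range"]))

    def subset(self, range_label: str) -> "OccurrenceSet":
        mask = (self.data["range"] == range_label).to_numpy()
        return self._take(np.flatnonzero(mask))

    def _take(self, idx: np.ndarray) -> "OccurrenceSet":
        env = self.env.iloc[idx] if self.env is not None else None
        return OccurrenceSet(
            data=self.data.iloc[idx],
            env=env,
            provenance=self.provenance,
            report=dict(self.report),
        )

    @staticmethod
    def concat(parts: Iterable["OccurrenceSet"]) -> "OccurrenceSet":
        parts = list(parts)
        data = pd.concat([p.data for p in parts], ignore_index=True)
        envs = [p.env for p in parts]
        env = None
        if all(e is not None for e in envs):
            env = pd.concat(envs, ignore_index=True)
        return OccurrenceSet(
            data=data, env=env, provenance="; ".join(p.provenance for p in parts)
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        out = self.data
        if self.env is not None:
            out = pd.concat([self.data, self.env], axis=1)
        out.to_csv(path, index=False)


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> Optional[str]:
    lowered = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    return None


def load_occurrences(
    path: str | os.PathLike,
    range_label: str,
    sep: str = ",",
) -> OccurrenceSet:
    """Read a delimited occurrence file and validate its coordinates.

    Recognizes plain ``lon``/``lat`` headers as well as the GBIF dialect
    ``decimalLongitude``/``decimalLatitude`` (case-insensitive).  Rows
    with unparsable or out-of-range coordinates are dropped and counted
    in the returned set's ``report``; row order is preserved.
    """
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no records")
    lon_col = _find_column(df.columns, _LON_ALIASES)
    lat_col = _find_column(df.columns, _LAT_ALIASES)
    if lon_col is None or lat_col is None:
        raise ValueError(f"{path}: no recognizable longitude/latitude columns")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    valid = (
        lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    ).to_numpy()
    n_invalid = int((~valid).sum())
    kept = df.loc[valid]
    if kept.empty:
        raise ValueError(f"{path}: no records with valid coordinates")
    data = pd.DataFrame(
        {
            "id": np.arange(len(kept)),
            "species": kept.get("species", pd.Series(["unknown"] * len(kept))).to_numpy(),
            "lon": lon[valid].to_numpy(),
            "lat": lat[valid].to_numpy(),
            "range": range_label,
        }
    )
    return OccurrenceSet(
        data=data,
        provenance=f"loaded from {os.fspath(path)}",
        report={"n_input": len(df), "n_valid": len(kept), "n_invalid_coords": n_invalid},
    )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(
    occ: OccurrenceSet,
    min_dist_km: float = 1.0,
    mode: str = "haversine",
    cell_size_deg: float = 0.5 / 60.0,
) -> OccurrenceSet:
    """Remove near-duplicate records within ``min_dist_km`` of each other.

    Greedy first-come retention in input order, applied independently
    per range label: a record is kept iff its distance to every
    already-kept record of the same range is >= ``min_dist_km``
    (boundary inclusive).  ``mode='grid'`` instead deduplicates by
    shared raster-cell identity at ``cell_size_deg`` resolution (the
    alternative reading of a "within 1 km" rule on ~1-km rasters).
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    if mode not in ("haversine", "grid"):
        raise ValueError(f"unknown thinning mode {mode!r}")
    lon = occ.data["lon"].to_numpy(dtype=float)
    lat = occ.data["lat"].to_numpy(dtype=float)
    ranges = occ.data["range"].to_numpy()
    keep_idx: list[int] = []
    # tolerate float roundoff at the inclusive boundary
    threshold = min_dist_km * (1.0 - 1e-9)
    for label in pd.unique(ranges):
        idx = np.flatnonzero(ranges == label)
        if mode == "grid":
            seen: set[tuple[int, int]] = set()
            for i in idx:
                cell = (
                    int(np.floor(lon[i] / cell_size_deg)),
                    int(np.floor(lat[i] / cell_size_deg)),
                )
                if cell not in seen:
                    seen.add(cell)
                    keep_idx.append(i)
            continue
        kept_lon: list[float] = []
        kept_lat: list[float] = []
        for i in idx:
            if kept_lon:
                d = haversine_km(
                    lon[i], lat[i], np.asarray(kept_lon), np.asarray(kept_lat)
                )
                if np.any(d < threshold):
                    continue
            kept_lon.append(lon[i])
            kept_lat.append(lat[i])
            keep_idx.append(i)
    keep = np.sort(np.asarray(keep_idx, dtype=int))
    out = occ._take(keep)
    out.report = dict(occ.report)
    out.report.update(
        {
            "n_before_thinning": len(occ),
            "n_after_thinning": len(keep),
            "min_dist_km": min_dist_km,
            "thinning_mode": mode,
        }
    )
    return out


def extract_env(occ: OccurrenceSet, grid: ClimateGrid) -> OccurrenceSet:
    """Annotate records with every layer's value at their containing cell.

    Records outside the grid extent or in no-data cells are dropped and
    counted in the report.  Raises if no record falls on the grid.
    """
    values, inside = grid.values_at(
        occ.data["lon"].to_numpy(), occ.data["lat"].to_numpy()
    )
    if not inside.any():
        raise ValueError("all records fall outside the grid extent")
    complete = values.notna().all(axis=1).to_numpy()
    keep = inside & complete
    if not keep.any():
        raise ValueError("all records fall in no-data cells")
    out = OccurrenceSet(
        data=occ.data.loc[keep],
        env=values.loc[keep],
        provenance=occ.provenance,
        report=dict(occ.report),
    )
    out.report.update(
        {
            "n_off_grid": int((~inside).sum()),
            "n_nodata": int((inside & ~complete).sum()),
            "n_annotated": int(keep.sum()),
        }
    )
    return out
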