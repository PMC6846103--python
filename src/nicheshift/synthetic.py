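"""Virtual-species scenario generator.

Everything downstream of this module (ordination, overlap statistics,
permutation tests, suitability models, physiology links) is exercised on
scenarios produced here, where the true niche is known.  A scenario
consists of

* two study regions ("native" and "introduced") of spatially
  autocorrelated bioclimatic rasters (smoothed white noise, rescaled per
  variable to ecologically plausible ranges, e.g. annual mean
  temperature between 7 and 20 degC),
* presence samples drawn from an axis-aligned Gaussian niche defined in
  climate units (optionally shifted between ranges, optionally with a
  one-knob sampling-bias surface), and
* a long-format physiological marker table with range x temperature
  dependent means and Gaussian noise, mimicking a garden chilling
  experiment.

All generators are pure functions of (config, seed); random sub-streams
are derived from the scenario seed by fixed offsets so each stage is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import ClimateGrid
from .occurrences import OccurrenceSet

__all__ = [
    "BIOCLIM_RANGES",
    "MARKER_VARIABLES",
    "EXPERIMENT1_TEMPERATURES",
    "ScenarioConfig",
    "VirtualNiche",
    "ShiftScenario",
    "generate_climate",
    "sample_occurrences",
    "make_shift_scenario",
    "generate_phys_table",
]

#: Plausible per-variable value ranges used when rescaling the smoothed
#: noise fields.  Temperatures in degC, precipitation in mm, following
#: the standard bioclim variable semantics.
BIOCLIM_RANGES: Dict[str, tuple[float, float]] = {
    "bio1": (7.0, 20.0),     # annual mean temperature
    "bio2": (5.0, 15.0),     # mean diurnal range
    "bio3": (25.0, 60.0),    # isothermality
    "bio4": (200.0, 800.0),  # temperature seasonality
    "bio5": (18.0, 35.0),    # max temperature of warmest month
    "bio6": (-5.0, 10.0),    # min temperature of coldest month
    "bio7": (10.0, 35.0),    # temperature annual range
    "bio8": (5.0, 22.0),
    "bio9": (2.0, 25.0),
    "bio10": (12.0, 28.0),
    "bio11": (0.0, 13.0),    # mean temperature of coldest quarter
    "bio12": (100.0, 1500.0),  # annual precipitation
    "bio13": (20.0, 250.0),
    "bio14": (0.0, 60.0),
    "bio15": (10.0, 100.0),
    "bio16": (50.0, 600.0),
    "bio17": (5.0, 150.0),
    "bio18": (10.0, 300.0),
    "bio19": (20.0, 500.0),
}

#: Physiological marker variables of the garden/chamber experiments.
MARKER_VARIABLES = (
    "H", "gs", "Fv/Fm", "PhiPSII", "ChlT", "Chl a/b", "VAZ",
    "DPS", "Zx", "Lut", "bCar", "aToc", "VAZ/ChlT",
)

#: Mean air temperatures (degC) of the five garden sampling days.
EXPERIMENT1_TEMPERATURES = (10.3, 10.6, 4.7, 8.6, 12.6)

# Latent-field loadings: bioclim layers are generated as mixtures of two
# shared latent surfaces (a thermal field T and a moisture field P) plus
# layer-specific smoothed noise, reproducing the strong inter-layer
# correlation of real bioclim stacks (which is what makes a 2-D PCA-env
# meaningful).  Values are the weight on (T, P); residual weight goes to
# the layer's own noise field.
_LATENT_LOADINGS: Dict[str, tuple[float, float]] = {
    "bio1": (0.90, 0.0), "bio2": (0.40, 0.0), "bio3": (0.40, 0.0),
    "bio4": (-0.60, 0.0), "bio5": (0.85, 0.0), "bio6": (0.85, 0.0),
    "bio7": (-0.50, 0.0), "bio8": (0.80, 0.0), "bio9": (0.80, 0.0),
    "bio10": (0.85, 0.0), "bio11": (0.90, 0.0),
    "bio12": (0.0, 0.90), "bio13": (0.0, 0.85), "bio14": (0.0, 0.80),
    "bio15": (0.0, -0.50), "bio16": (0.0, 0.85), "bio17": (0.0, 0.80),
    "bio18": (0.0, 0.75), "bio19": (0.0, 0.80),
}

# Region metadata: (x_origin, y_origin) in decimal degrees, desk-scale
# stands-ins for a South-African native and European introduced window.
_REGION_ORIGINS = {"native": (18.0, -30.0), "introduced": (-10.0, 55.0)}
# Fixed sub-stream offsets: climate native/introduced, occurrences
# native/introduced, physiology.
_STREAMS = {
    "climate_native": 0,
    "climate_introduced": 1,
    "occ_native": 2,
    "occ_introduced": 3,
    "phys": 4,
}


@dataclass
class VirtualNiche:
    """Axis-aligned Gaussian niche in climate units (not PCA units).

    ``suitability(x) = max_prob * exp(-0.5 * sum_k ((x_k - c_k)/s_k)^2)``
    so suitability at the center equals ``max_prob`` and decreases
    monotonically with Mahalanobis distance from it.
    """

    variables: tuple[str, ...]
    center: np.ndarray
    sd: np.ndarray
    max_prob: float = 1.0

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.center = np.asarray(self.center, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.center.shape != self.sd.shape or self.center.ndim != 1:
            raise ValueError("center and sd must be 1-D vectors of equal length")
        if len(self.variables) != self.center.size:
            raise ValueError("variables and center length disagree")
        if np.any(self.sd <= 0):
            raise ValueError("niche sd must be strictly positive")
        if not (0 < self.max_prob <= 1):
            raise ValueError("max_prob must lie in (0, 1]")

    def suitability(self, env) -> np.ndarray:
        """Suitability in [0, max_prob] for rows of environment values."""
        if isinstance(env, pd.DataFrame):
            env = env[list(self.variables)].to_numpy()
        env = np.asarray(env, dtype=float)
        z = (env - self.center) / self.sd
        return self.max_prob * np.exp(-0.5 * np.sum(z * z, axis=-1))


@dataclass
class ScenarioConfig:
    """Parameters of a two-range virtual-species scenario.

    The defaults are the study conditions the pipeline is validated
    under: sample sizes 52 (native) and 492 (introduced) occurrences and
    a 2-SD niche shift toward colder annual mean temperature in the
    introduced range.
    """

    region_shape: tuple[int, int] = (60, 60)
    n_env_layers: int = 19
    autocorr_scale: float = 5.0
    niche_vars: tuple[str, ...] = ("bio1", "bio12")
    niche_center_native: Sequence[float] = (13.0, 800.0)
    niche_center_introduced: Sequence[float] | None = None
    niche_sd: Sequence[float] = (2.5, 250.0)
    shift_magnitude: float = 2.0
    shift_direction: Sequence[float] = (-1.0, 0.0)
    n_occ_native: int = 52
    n_occ_introduced: int = 492
    bias_strength: float = 0.0
    introduced_cooling: float = 0.0
    shared_landscape: bool = False
    max_prob: float = 1.0
    cell_size: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_shape = tuple(int(v) for v in self.region_shape)
        if len(self.region_shape) != 2 or min(self.region_shape) <= 0:
            raise ValueError("region_shape must be two positive integers")
        if self.n_env_layers <= 0:
            raise ValueError("n_env_layers must be positive")
        if self.autocorr_scale < 0:
            raise ValueError("autocorr_scale must be >= 0")
        if self.autocorr_scale >= min(self.region_shape):
            raise ValueError("autocorr_scale must be smaller than the region")
        if self.n_occ_native <= 0 or self.n_occ_introduced <= 0:
            raise ValueError("occurrence counts must be positive")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.shared_landscape and self.introduced_cooling != 0:
            raise ValueError("introduced_cooling conflicts with shared_landscape")
        self.niche_vars = tuple(self.niche_vars)
        names = set(self.layer_names)
        missing = [v for v in self.niche_vars if v not in names]
        if missing:
            raise ValueError(
                f"niche variables {missing} not among the {self.n_env_layers} layers"
            )
        cn = np.asarray(self.niche_center_native, dtype=float)
        sd = np.asarray(self.niche_sd, dtype=float)
        if np.any(sd <= 0):
            raise ValueError("niche_sd must be strictly positive elementwise")
        if cn.shape != sd.shape or cn.size != len(self.niche_vars):
            raise ValueError("niche center/sd must match niche_vars in length")
        if self.niche_center_introduced is None:
            d = np.asarray(self.shift_direction, dtype=float)
            norm = np.linalg.norm(d)
            if norm == 0:
                raise ValueError("shift_direction must be non-zero")
            ci = cn + self.shift_magnitude * sd * (d / norm)
            self.niche_center_introduced = tuple(ci)
        else:
            ci = np.asarray(self.niche_center_introduced, dtype=float)
            dist = np.linalg.norm((ci - cn) / sd)
            if not math.isclose(dist, self.shift_magnitude, abs_tol=1e-6):
                raise ValueError(
                    "shift_magnitude inconsistent with the distance between "
                    f"niche centers in SD units ({dist:.6f} vs {self.shift_magnitude})"
                )
        self.niche_center_native = tuple(cn)
        self.niche_sd = tuple(sd)

    @property
    def layer_names(self) -> list[str]:
        return [f"bio{i}" for i in range(1, self.n_env_layers + 1)]

    def niche(self, region_id: str) -> VirtualNiche:
        center = (
            self.niche_center_native
            if region_id == "native"
            else self.niche_center_introduced
        )
        return VirtualNiche(self.niche_vars, center, self.niche_sd, self.max_prob)

    def to_dict(self) -> dict:
        return {
            "region_shape": list(self.region_shape),
            "n_env_layers": self.n_env_layers,
            "autocorr_scale": self.autocorr_scale,
            "niche_vars": list(self.niche_vars),
            "niche_center_native": list(self.niche_center_native),
            "niche_center_introduced": list(self.niche_center_introduced),
            "niche_sd": list(self.niche_sd),
            "shift_magnitude": self.shift_magnitude,
            "shift_direction": list(self.shift_direction),
            "n_occ_native": self.n_occ_native,
            "n_occ_introduced": self.n_occ_introduced,
            "bias_strength": self.bias_strength,
            "introduced_cooling": self.introduced_cooling,
            "shared_landscape": self.shared_landscape,
            "max_prob": self.max_prob,
            "cell_size": self.cell_size,
            "seed": self.seed,
        }


class ShiftScenario(NamedTuple):
    grid_native: ClimateGrid
    grid_introduced: ClimateGrid
    occ_native: OccurrenceSet
    occ_introduced: OccurrenceSet
    niche_native: VirtualNiche
    niche_introduced: VirtualNiche


def _rng(seed, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


def _variable_range(config: ScenarioConfig, name: str, region_id: str):
    lo, hi = BIOCLIM_RANGES.get(name, (0.0, 1.0))
    # Optionally extend the cold end of the temperature layers so the
    # introduced region offers colder climates than the native one.
    if region_id == "introduced" and name in ("bio1", "bio11", "bio6"):
        lo -= config.introduced_cooling
    return lo, hi


def generate_climate(config: ScenarioConfig, region_id: str) -> ClimateGrid:
    """Generate one region's stack of autocorrelated climate rasters.

    Each layer is white noise smoothed with a Gaussian kernel of scale
    ``autocorr_scale`` cells and affinely rescaled to the variable's
    stated min/max.  Bit-identical for a given (config, seed, region).
    """
    if region_id not in _REGION_ORIGINS:
        raise ValueError(f"region_id must be 'native' or 'introduced', got {region_id!r}")
    # shared_landscape: both regions reuse the native climate realization,
    # making the two ranges' available environments identical -- the
    # exchangeable-null condition required to calibrate the equivalence test.
    stream = "climate_native" if config.shared_landscape else f"climate_{region_id}"
    rng = _rng(config.seed, _STREAMS[stream])
    rows, cols = config.region_shape

    def smooth_noise() -> np.ndarray:
        f = rng.standard_normal((rows, cols))
        if config.autocorr_scale > 0:
            f = gaussian_filter(f, sigma=config.autocorr_scale, mode="reflect")
            sd = f.std()
            if sd > 0:
                f = f / sd
        return f

    latent_t = smooth_noise()
    latent_p = smooth_noise()
    layers: Dict[str, np.ndarray] = {}
    for name in config.layer_names:
        wt, wp = _LATENT_LOADINGS.get(name, (0.0, 0.0))
        w_own = np.sqrt(max(0.0, 1.0 - wt * wt - wp * wp))
        fieldv = wt * latent_t + wp * latent_p + w_own * smooth_noise()
        lo, hi = _variable_range(config, name, region_id)
        span = np.ptp(fieldv)
        if span == 0:  # pathological flat field
            fieldv = np.full_like(fieldv, 0.5 * (lo + hi))
        else:
            fieldv = lo + (fieldv - fieldv.min()) * (hi - lo) / span
        layers[name] = fieldv
    x0, y0 = _REGION_ORIGINS[region_id]
    return ClimateGrid(layers, x0, y0, config.cell_size, region=region_id)


def sample_occurrences(
    grid: ClimateGrid,
    niche: VirtualNiche,
    n: int,
    bias_strength: float = 0.0,
    seed: int | Sequence[int] = 0,
) -> OccurrenceSet:
    """Draw presence records from a grid with probability ~ suitability x bias.

    The bias surface is ``exp(bias_strength * z(first layer))`` where ``z``
    standardizes the region's first bioclim layer -- a one-knob stand-in
    for geographically uneven sampling effort.  Records are placed at
    cell centers and come annotated with every layer's value.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    missing = [v for v in niche.variables if v not in grid.layers]
    if missing:
        raise ValueError(f"grid lacks niche variables {missing}")
    rng = np.random.default_rng(seed)
    env = grid.env_table()
    if env.empty:
        raise ValueError("grid has no valid cells")
    weights = niche.suitability(env)
    if bias_strength > 0:
        first = env[grid.layer_names[0]].to_numpy()
        sd = first.std()
        z = (first - first.mean()) / (sd if sd > 0 else 1.0)
        weights = weights * np.exp(bias_strength * z)
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("empty support: niche suitability is zero over the grid")
    p = weights / total
    cells = rng.choice(env.index.to_numpy(), size=n, replace=True, p=p)
    coords = grid.coords_table().loc[cells]
    data = pd.DataFrame(
        {
            "id": np.arange(n),
            "species": "virtual",
            "lon": coords["lon"].to_numpy(),
            "lat": coords["lat"].to_numpy(),
            "range": grid.region or "unknown",
        }
    )
    env_rows = env.loc[cells].reset_index(drop=True)
    return OccurrenceSet(
        data=data,
        env=env_rows,
        provenance=f"virtual species sample (n={n}, bias={bias_strength})",
    )


def make_shift_scenario(config: ScenarioConfig) -> ShiftScenario:
    """Build the full two-range scenario: grids, samples and true niches."""
    grid_nat = generate_climate(config, "native")
    grid_int = generate_climate(config, "introduced")
    niche_nat = config.niche("native")
    niche_int = config.niche("introduced")
    occ_nat = sample_occurrences(
        grid_nat,
        niche_nat,
        config.n_occ_native,
        config.bias_strength,
        seed=[config.seed, _STREAMS["occ_native"]],
    )
    occ_int = sample_occurrences(
        grid_int,
        niche_int,
        config.n_occ_introduced,
        config.bias_strength,
        seed=[config.seed, _STREAMS["occ_introduced"]],
    )
    return ShiftScenario(grid_nat, grid_int, occ_nat, occ_int, niche_nat, niche_int)


# -------------------------------------------------------------------- markers
# Default range x temperature mean structure: mean = base + cold_slope *
# max(0, 10 - T).  Chosen to reproduce the qualitative chilling pattern
# of the experiments: chlorophylls and hydration drop in the cold while
# de-epoxidation (DPS, Zx) and the tocopherol pool rise, with the
# native range responding more strongly (notably aToc and Zx).
DEFAULT_MARKER_EFFECTS: Dict[str, Dict[str, tuple[float, float]]] = {
    "H":        {"native": (4.0, -0.15), "introduced": (4.0, -0.10)},
    "gs":       {"native": (150.0, -10.0), "introduced": (150.0, -8.0)},
    "Fv/Fm":    {"native": (0.80, -0.006), "introduced": (0.80, -0.002)},
    "PhiPSII":  {"native": (0.60, -0.030), "introduced": (0.60, -0.020)},
    "ChlT":     {"native": (500.0, -25.0), "introduced": (500.0, -12.0)},
    "Chl a/b":  {"native": (3.0, 0.08), "introduced": (3.0, 0.05)},
    "VAZ":      {"native": (60.0, -2.0), "introduced": (60.0, -1.0)},
    "DPS":      {"native": (0.15, 0.040), "introduced": (0.15, 0.020)},
    "Zx":       {"native": (5.0, 1.50), "introduced": (5.0, 0.50)},
    "Lut":      {"native": (100.0, 2.0), "introduced": (100.0, 0.0)},
    "bCar":     {"native": (40.0, -1.0), "introduced": (40.0, -0.5)},
    "aToc":     {"native": (3.0, 0.80), "introduced": (3.0, 0.10)},
    "VAZ/ChlT": {"native": (0.12, 0.010), "introduced": (0.12, 0.005)},
}

_CHILL_THRESHOLD = 10.0  # degC below which the cold response engages


def _marker_mean(spec, temperature: float) -> float:
    """Resolve a mean specification at a temperature.

    ``spec`` may be a (base, cold_slope) pair, a plain scalar, a mapping
    ``{temperature: mean}`` or a callable ``mean(T)``.
    """
    if callable(spec):
        return float(spec(temperature))
    if isinstance(spec, Mapping):
        key = min(spec, key=lambda t: abs(float(t) - temperature))
        return float(spec[key])
    if np.isscalar(spec):
        return float(spec)
    base, slope = spec
    return float(base) + float(slope) * max(0.0, _CHILL_THRESHOLD - temperature)


def generate_phys_table(
    n_per_range: int = 6,
    effects: Mapping[str, Mapping[str, object]] | None = None,
    noise_sd: Mapping[str, float] | float | None = None,
    seed: int | Sequence[int] = 0,
    temperatures: Sequence[float] = EXPERIMENT1_TEMPERATURES,
) -> pd.DataFrame:
    """Long-format marker table (plant, range, temperature, variable, value).

    ``effects`` overrides the default mean structure per variable and
    range; ``noise_sd`` is the Gaussian measurement noise (default: 5 %
    of each variable's baseline mean).  With six plants per range and
    the five garden sampling temperatures the table mirrors the
    dimensions of the chilling experiment.
    """
    if n_per_range <= 0:
        raise ValueError("n_per_range must be positive")
    merged: Dict[str, Dict[str, object]] = {
        k: dict(v) for k, v in DEFAULT_MARKER_EFFECTS.items()
    }
    if effects:
        for var, per_range in effects.items():
            if var not in MARKER_VARIABLES:
                raise ValueError(f"unknown marker variable {var!r}")
            merged.setdefault(var, {})
            merged[var].update(per_range)
    if noise_sd is None:
        noise = {v: 0.05 * abs(DEFAULT_MARKER_EFFECTS[v]["native"][0]) for v in merged}
    elif np.isscalar(noise_sd):
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        noise = {v: float(noise_sd) for v in merged}
    else:
        unknown = set(noise_sd) - set(MARKER_VARIABLES)
        if unknown:
            raise ValueError(f"unknown marker variable {sorted(unknown)}")
        noise = {v: 0.0 for v in merged}
        noise.update({k: float(s) for k, s in noise_sd.items()})
        if any(s < 0 for s in noise.values()):
            raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for rng_label in ("native", "introduced"):
        for plant in range(n_per_range):
            plant_id = f"{rng_label}_{plant + 1}"
            for temp in temperatures:
                for var, per_range in merged.items():
                    mean = _marker_mean(per_range[rng_label], float(temp))
                    value = mean + rng.normal(0.0, noise[var])
                    rows.append(
                        (plant_id, rng_label, "garden", float(temp), var, value)
                    )
    return pd.DataFrame(
        rows, columns=["plant", "range", "context", "temperature", "variable", "value"]
    )
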