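"""Synthetic dynamic landscapes for eco-evolutionary simulations.

The simulation domain is a gridded, equal-area world whose temperature field
emulates the structure of Cenozoic paleoclimate reconstructions: a latitudinal
temperature gradient whose steepness changes through time, an additive global
temperature fluctuation curve, a lapse-rate correction for elevation, and a
subtropical arid belt.  Raw temperature and aridity fields are standardized
jointly over all time steps into [0, 1], so the global temperature curve is
preserved as temporal variation of the standardized field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LandscapeConfig",
    "LandscapeSeries",
    "raw_temperature",
    "standardize01",
    "generate_landscape",
    "interpolate_timesteps",
    "write_landscape",
    "read_landscape",
]

#: Sentinel used on non-habitable cells of standardized layers.
MISSING = np.nan


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.  Rows map to latitude bands from +90 to -90 degrees.
    cell_size_km
        Edge length of the (equal-area) square grid cells, default 220 km.
    n_steps
        Number of time steps of the dynamic landscape.
    dt_kyr
        Duration of one time step in kyr, default 170.
    equator_pole_gradient
        Per-step equator-to-pole temperature difference (degrees).  A series of
        length ``m <= n_steps`` is linearly interpolated onto the steps.  The
        default rises from 25 to 45 degrees, mimicking the steepening of the
        latitudinal gradient as the climate cooled over the Cenozoic.
    global_anomaly
        Per-step additive global temperature offset (degrees).  The default is
        a long-term cooling trend from +8 degrees with superimposed
        1.2-degree oscillations standing in for shorter climate cycles.
    lapse_rate
        Temperature decrease in degrees per km of elevation, default 6.5.
    arid_belt_rows
        Row indices carrying nonzero aridity.  Default: rows whose nominal
        latitude falls in the subtropical belts (15-35 degrees absolute).
    arid_amplitude
        Per-step multiplier of the arid-belt aridity, default all ones.
    elevation_seed, terrain_roughness, elevation_scale_km
        Controls of the static random elevation field: RNG seed, inverse
        smoothing length (larger = rougher terrain) and the km amplitude of
        one standard deviation of the smoothed field.
    land_fraction, continent_scale_cells
        Fraction of grid cells that are habitable land and the correlation
        length (in cells) of the smooth random field whose upper quantile
        defines the landmasses.  Ocean cells are non-habitable and carry the
        missing-value sentinel; they are the dispersal barriers that make
        geographic isolation (and hence allopatric speciation) possible.
        ``land_fraction=1`` restores an all-land world.
    rng_seed
        Seed for any remaining stochastic elements (kept for reproducibility
        contracts; the default generator is otherwise deterministic given
        ``elevation_seed``).
    """

    n_rows: int = 36
    n_cols: int = 18
    cell_size_km: float = 220.0
    n_steps: int = 120
    dt_kyr: float = 170.0
    equator_pole_gradient: Sequence[float] | None = None
    global_anomaly: Sequence[float] | None = None
    lapse_rate: float = 6.5
    arid_belt_rows: Sequence[int] | None = None
    arid_amplitude: Sequence[float] | None = None
    elevation_seed: int = 0
    terrain_roughness: float = 2.0
    elevation_scale_km: float = 2.5
    land_fraction: float = 0.28
    continent_scale_cells: float = 0.8
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be > 0")
        if not (0.0 < self.land_fraction <= 1.0):
            raise ValueError("land_fraction must be in (0, 1]")
        if self.lapse_rate < 0:
            raise ValueError("lapse_rate must be >= 0")
        for name in ("equator_pole_gradient", "global_anomaly", "arid_amplitude"):
            series = getattr(self, name)
            if series is not None:
                arr = np.asarray(series, dtype=float)
                if arr.ndim != 1 or arr.size < 1 or arr.size > self.n_steps:
                    raise ValueError(f"{name} must be 1-D with length in [1, n_steps]")
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{name} contains non-finite values")

    @property
    def latitude_deg(self) -> np.ndarray:
        """Nominal latitude of each row centre, +90 (row 0) to -90."""
        edges = np.linspace(90.0, -90.0, self.n_rows + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class LandscapeSeries:
    """A generated dynamic landscape.

    ``temperature01`` and ``aridity01`` are (n_steps, n_rows, n_cols) arrays in
    [0, 1] on habitable cells and NaN elsewhere; ``elevation_km`` is static.
    """

    temperature01: np.ndarray
    aridity01: np.ndarray
    elevation_km: np.ndarray
    habitable: np.ndarray
    latitude_deg: np.ndarray
    step_times_kyr: np.ndarray
    cell_size_km: float = 220.0

    @property
    def n_steps(self) -> int:
        return self.temperature01.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperature01.shape[1:]

    def validate(self) -> None:
        t, a, h = self.temperature01, self.aridity01, self.habitable
        if t.shape != a.shape or t.shape != h.shape:
            raise ValueError("temperature01, aridity01 and habitable must share shape")
        if self.elevation_km.shape != t.shape[1:]:
            raise ValueError("elevation_km shape does not match grid")
        if self.latitude_deg.shape != (t.shape[1],):
            raise ValueError("latitude_deg must have one entry per row")
        if self.step_times_kyr.shape != (t.shape[0],):
            raise ValueError("step_times_kyr must have one entry per step")
        hab = h.astype(bool)
        for name, layer in (("temperature01", t), ("aridity01", a)):
            vals = layer[hab]
            if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
                raise ValueError(f"{name} outside [0, 1] on habitable cells")


def raw_temperature(
    latitude_deg: np.ndarray,
    gradient: float,
    anomaly: float,
    elevation_km: np.ndarray,
    lapse_rate: float = 6.5,
) -> np.ndarray:
    """Raw (unstandardized) temperature field for one time step.

    The latitudinal band value is ``cos(latitude)`` (1 at the equator, 0 at the
    poles), scaled by the gradient steepness and offset by the global anomaly;
    elevation cools cells linearly at ``lapse_rate`` degrees per km.
    """
    lat = np.asarray(latitude_deg, dtype=float)
    elev = np.asarray(elevation_km, dtype=float)
    band = np.cos(np.radians(lat))
    return band[:, None] * float(gradient) + float(anomaly) - lapse_rate * elev


def standardize01(raw: np.ndarray) -> np.ndarray:
    """Affinely map an array (or grid time series) into [0, 1].

    Bounds are the global min/max over all finite values (all steps jointly),
    so temporal fluctuation survives standardization.  A constant field maps to
    0.5 everywhere by convention.  NaNs (non-habitable sentinel) pass through.
    """
    raw = np.asarray(raw, dtype=float)
    finite = np.isfinite(raw)
    if not finite.any():
        raise ValueError("standardize01: no finite values")
    lo = raw[finite].min()
    hi = raw[finite].max()
    if hi == lo:
        out = np.full_like(raw, 0.5)
        out[~finite] = MISSING
        return out
    out = (raw - lo) / (hi - lo)
    out[~finite] = MISSING
    return out


def _resample_series(series: Sequence[float] | None, n_steps: int, default: np.ndarray) -> np.ndarray:
    if series is None:
        return default
    arr = np.asarray(series, dtype=float)
    if arr.size == n_steps:
        return arr
    if arr.size == 1:
        return np.full(n_steps, arr[0])
    # linear interpolation of a shorter control series onto the model steps
    return np.interp(np.linspace(0.0, 1.0, n_steps), np.linspace(0.0, 1.0, arr.size), arr)


def _default_gradient(n_steps: int) -> np.ndarray:
    return np.linspace(25.0, 45.0, n_steps)


def _default_anomaly(n_steps: int) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n_steps)
    return 8.0 * (1.0 - s) ** 1.5 + 1.2 * np.sin(2.0 * np.pi * 5.0 * s)


def _elevation_field(config: LandscapeConfig) -> np.ndarray:
    rng = np.random.default_rng(config.elevation_seed)
    z = rng.standard_normal((config.n_rows, config.n_cols))
    sigma = max(0.5, 1.5 / max(config.terrain_roughness, 1e-6))
    z = ndimage.gaussian_filter(z, sigma=sigma, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = z / sd
    # only positive anomalies become land relief; the rest is lowland at 0 km
    return np.maximum(z, 0.0) * config.elevation_scale_km


def _land_mask(config: LandscapeConfig) -> np.ndarray:
    """Static continent mask from a smooth random field's upper quantile."""
    if config.land_fraction >= 1.0:
        return np.ones((config.n_rows, config.n_cols), dtype=bool)
    rng = np.random.default_rng(config.elevation_seed + 1_000_003)
    z = rng.standard_normal((config.n_rows, config.n_cols))
    z = ndimage.gaussian_filter(z, sigma=config.continent_scale_cells, mode="wrap")
    cut = np.quantile(z, 1.0 - config.land_fraction)
    return z >= cut


def generate_landscape(config: LandscapeConfig) -> LandscapeSeries:
    """Generate a dynamic landscape from a :class:`LandscapeConfig`.

    Raw temperature at a cell is ``band(latitude) * gradient(t) + anomaly(t) -
    lapse_rate * elevation``; raw aridity is the arid-belt indicator scaled by a
    per-step amplitude.  Both fields are standardized into [0, 1] with bounds
    taken over all steps jointly.  Bit-reproducible for a fixed configuration.
    """
    config.validate()
    n_steps = config.n_steps
    lat = config.latitude_deg
    gradient = _resample_series(config.equator_pole_gradient, n_steps, _default_gradient(n_steps))
    anomaly = _resample_series(config.global_anomaly, n_steps, _default_anomaly(n_steps))
    arid_amp = _resample_series(config.arid_amplitude, n_steps, np.ones(n_steps))

    land = _land_mask(config)
    elevation = _elevation_field(config) * land
    habitable = np.broadcast_to(land, (n_steps, config.n_rows, config.n_cols)).copy()

    raw_t = np.empty((n_steps, config.n_rows, config.n_cols))
    for t in range(n_steps):
        raw_t[t] = raw_temperature(lat, gradient[t], anomaly[t], elevation, config.lapse_rate)
    if not np.all(np.isfinite(raw_t)):
        raise ValueError("generated raw temperature contains non-finite values")
    raw_t[:, ~land] = MISSING

    if config.arid_belt_rows is None:
        belt = (np.abs(lat) >= 15.0) & (np.abs(lat) <= 35.0)
    else:
        belt = np.zeros(config.n_rows, dtype=bool)
        belt[np.asarray(config.arid_belt_rows, dtype=int)] = True
    raw_a = np.zeros_like(raw_t)
    raw_a[:, belt, :] = arid_amp[:, None, None]
    raw_a[:, ~land] = MISSING

    temperature01 = standardize01(raw_t)
    aridity01 = standardize01(raw_a)

    series = LandscapeSeries(
        temperature01=temperature01,
        aridity01=aridity01,
        elevation_km=elevation,
        habitable=habitable,
        latitude_deg=lat,
        step_times_kyr=np.arange(n_steps, dtype=float) * config.dt_kyr,
        cell_size_km=config.cell_size_km,
    )
    series.validate()
    return series


def interpolate_timesteps(series: LandscapeSeries, target_n: int) -> LandscapeSeries:
    """Linearly interpolate a landscape onto ``target_n`` time steps.

    Endpoints are preserved exactly; habitability is interpolated as a
    >= 0.5 vote between bracketing steps.
    """
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    n = series.n_steps
    if n < 2:
        raise ValueError("series must have at least 2 steps to interpolate")
    if target_n < n:
        raise ValueError("target_n must be >= the current number of steps")
    if target_n == n:
        return series

    pos = np.linspace(0.0, n - 1.0, target_n)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = (pos - lo)[:, None, None]

    def lerp(layer: np.ndarray) -> np.ndarray:
        return layer[lo] * (1.0 - w) + layer[hi] * w

    times = np.interp(pos, np.arange(n), series.step_times_kyr)
    return LandscapeSeries(
        temperature01=lerp(series.temperature01),
        aridity01=lerp(series.aridity01),
        elevation_km=series.elevation_km.copy(),
        habitable=lerp(series.habitable.astype(float)) >= 0.5,
        latitude_deg=series.latitude_deg.copy(),
        step_times_kyr=times,
        cell_size_km=series.cell_size_km,
    )


# ---------------------------------------------------------------------------
# serialization: one self-describing array container (.npz) or a plain-text
# per-step CSV grid dialect (a directory with one file per layer per step)
# ---------------------------------------------------------------------------

_CSV_LAYERS = ("temperature01", "aridity01", "habitable")


def write_landscape(series: LandscapeSeries, path: str | Path) -> Path:
    """Write a landscape either as a ``.npz`` container or a CSV directory."""
    path = Path(path)
    series.validate()
    if path.suffix == ".npz":
        np.savez(
            path,
            temperature01=series.temperature01,
            aridity01=series.aridity01,
            elevation_km=series.elevation_km,
            habitable=series.habitable,
            latitude_deg=series.latitude_deg,
            step_times_kyr=series.step_times_kyr,
            cell_size_km=np.array([series.cell_size_km]),
        )
        return path
    path.mkdir(parents=True, exist_ok=True)
    for name in _CSV_LAYERS:
        layer = getattr(series, name)
        for t in range(series.n_steps):
            np.savetxt(path / f"{name}_step{t:04d}.csv", layer[t].astype(float), delimiter=",")
    np.savetxt(path / "elevation_km.csv", series.elevation_km, delimiter=",")
    np.savetxt(path / "latitude_deg.csv", series.latitude_deg, delimiter=",")
    np.savetxt(path / "step_times_kyr.csv", series.step_times_kyr, delimiter=",")
    np.savetxt(path / "cell_size_km.csv", np.array([series.cell_size_km]), delimiter=",")
    return path


def _read_csv_layer(path: Path, name: str, t: int) -> np.ndarray:
    f = path / f"{name}_step{t:04d}.csv"
    try:
        return np.atleast_2d(np.loadtxt(f, delimiter=","))
    except Exception as exc:  # pragma: no cover - error path
        raise ValueError(f"malformed landscape file for layer {name!r}, step {t}: {exc}") from exc


def read_landscape(path: str | Path) -> LandscapeSeries:
    """Read a landscape written by :func:`write_landscape`.

    A missing habitability layer defaults to all-habitable with a warning.
    Mismatched grid shapes between steps raise a parse error naming the
    offending layer and step.
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".npz":
        with np.load(path) as data:
            if "habitable" in data:
                habitable = data["habitable"].astype(bool)
            else:
                warnings.warn("landscape file has no habitability layer; defaulting to all-habitable")
                habitable = np.ones_like(data["temperature01"], dtype=bool)
            series = LandscapeSeries(
                temperature01=data["temperature01"],
                aridity01=data["aridity01"],
                elevation_km=data["elevation_km"],
                habitable=habitable,
                latitude_deg=data["latitude_deg"],
                step_times_kyr=data["step_times_kyr"],
                cell_size_km=float(data["cell_size_km"][0]) if "cell_size_km" in data else 220.0,
            )
    else:
        times = np.atleast_1d(np.loadtxt(path / "step_times_kyr.csv", delimiter=","))
        n_steps = times.size
        layers: dict[str, np.ndarray] = {}
        for name in ("temperature01", "aridity01"):
            steps = [_read_csv_layer(path, name, t) for t in range(n_steps)]
            shapes = {s.shape for s in steps}
            if len(shapes) > 1:
                raise ValueError(f"mismatched grid shapes across steps in layer {name!r}: {sorted(shapes)}")
            layers[name] = np.stack(steps)
        if (path / "habitable_step0000.csv").exists():
            hab = np.stack([_read_csv_layer(path, "habitable", t) for t in range(n_steps)]) >= 0.5
        else:
            warnings.warn("no habitability layer found; defaulting to all-habitable")
            hab = np.ones_like(layers["temperature01"], dtype=bool)
        cell_file = path / "cell_size_km.csv"
        cell_size = float(np.atleast_1d(np.loadtxt(cell_file, delimiter=","))[0]) if cell_file.exists() else 220.0
        series = LandscapeSeries(
            temperature01=layers["temperature01"],
            aridity01=layers["aridity01"],
            elevation_km=np.atleast_2d(np.loadtxt(path / "elevation_km.csv", delimiter=",")),
            habitable=hab,
            latitude_deg=np.atleast_1d(np.loadtxt(path / "latitude_deg.csv", delimiter=",")),
            step_times_kyr=times,
            cell_size_km=cell_size,
        )
    if series.temperature01.shape != series.aridity01.shape:
        raise ValueError("mismatched grid shapes between temperature01 and aridity01")
    series.validate()
    return series
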