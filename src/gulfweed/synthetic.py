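"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of (config, seed):

* :func:`gen_tissue_dataset` — tissue tables with the schema of the real
  deposit: era group sizes matching the observed record counts (200 from
  2021, 20 from 1983-1987, 21 from 2015-2018), %P log-uniform over a
  realistic dry-weight range, arsenic built from a configurable power law
  As:P = 10^a * (%P)^b with multiplicative lognormal noise, and regional
  offsets in %N, %P and d15N reproducing the qualitative field contrasts
  (GASB tissue N,P-enriched; Sargasso Sea P-poor; northern Sargasso Sea
  d15N ~ +2 permil).
* :func:`gen_field` — analytic velocity fields (uniform, solid-body
  rotation, double gyre) with a closed-form trajectory evaluator where one
  exists, so the tracker can be validated against exact solutions.
* :func:`gen_stations` — release-site lists inside a lon/lat box.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fields import GriddedField
from .tracking import R_EARTH

__all__ = [
    "TissueGenConfig",
    "FieldGenConfig",
    "gen_tissue_dataset",
    "gen_field",
    "gen_stations",
]

_DEG = np.pi / 180.0

# lon/lat sampling boxes nested strictly inside the default region scheme
_REGION_BOXES = {
    "NSS": (-70.0, -50.0, 30.5, 37.5),
    "SS": (-70.0, -50.0, 22.5, 29.5),
    "CAR": (-85.0, -65.0, 13.0, 21.0),
    "WTA": (-68.0, -49.0, 3.0, 11.5),
}

_ERA_DATES = {
    "y2021": ("2021-03-16", "2021-05-16"),
    "y1983_1987": ("1983-01-01", "1987-12-31"),
    "y2015_2018": ("2015-01-01", "2018-12-31"),
}


@dataclass(frozen=True)
class TissueGenConfig:
    """Ground truth for synthetic tissue tables.

    ``b_true``/``log10_intercept`` define the As:P (weight basis) power law
    in %P; ``noise_sd`` is the lognormal scatter in log10 units.  Regional
    offset dicts shift %N (additive, % dry wt), log10(%P) (additive in log
    space) and d15N (additive, permil).
    """

    n_2021: int = 200
    n_1983_1987: int = 20
    n_2015_2018: int = 21
    b_true: float = -1.3
    log10_intercept: float = -2.4
    p_range: tuple[float, float] = (0.01, 0.3)
    noise_sd: float = 0.15
    region_weights: dict = dc_field(
        default_factory=lambda: {"NSS": 0.15, "SS": 0.35, "CAR": 0.20, "WTA": 0.30}
    )
    n_offsets: dict = dc_field(
        default_factory=lambda: {"NSS": 0.20, "SS": -0.25, "CAR": 0.30, "WTA": 0.30}
    )
    p_log10_offsets: dict = dc_field(
        default_factory=lambda: {"NSS": 0.0, "SS": -0.15, "CAR": 0.10, "WTA": 0.10}
    )
    d15n_means: dict = dc_field(
        default_factory=lambda: {"NSS": 2.0, "SS": -0.5, "CAR": -0.5, "WTA": 1.0}
    )
    d15n_sd: float = 0.7
    c_mean: float = 27.0
    c_sd: float = 2.5
    n_base: float = 0.9
    n_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.p_range[0] <= 0 or self.p_range[1] <= self.p_range[0]:
            raise ConfigError("p_range must be positive and increasing")
        if min(self.n_2021, self.n_1983_1987, self.n_2015_2018) < 0:
            raise ConfigError("era counts must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def gen_tissue_dataset(config: TissueGenConfig | None = None) -> pd.DataFrame:
    """Generate a tissue table (canonical schema) with known power-law truth.

    2021 samples are spread over the four regions by ``region_weights``;
    archive-era samples (1983-1987, 2015-2018) sit in the Sargasso Sea, the
    provenance of the historical specimens.  Arsenic is derived from the
    configured As:P power law on the weight basis and converted to ug/g.
    """
    config = config or TissueGenConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    era_specs = [
        ("y2021", config.n_2021, None),
        ("y1983_1987", config.n_1983_1987, "SS"),
        ("y2015_2018", config.n_2015_2018, "SS"),
    ]
    regions = list(config.region_weights)
    weights = np.array([config.region_weights[r] for r in regions], dtype=float)
    weights = weights / weights.sum()
    counter = 0
    for era, n, fixed_region in era_specs:
        for _ in range(n):
            region = fixed_region or rng.choice(regions, p=weights)
            lon_w, lon_e, lat_s, lat_n = _REGION_BOXES[region]
            lon = rng.uniform(lon_w, lon_e)
            lat = rng.uniform(lat_s, lat_n)
            lo, hi = np.log10(config.p_range[0]), np.log10(config.p_range[1])
            log_p = rng.uniform(lo, hi) + config.p_log10_offsets.get(region, 0.0)
            pct_p = 10.0 ** log_p
            log_ratio = (
                config.log10_intercept
                + config.b_true * np.log10(pct_p)
                + rng.normal(0.0, config.noise_sd)
            )
            as_ug_g = 10.0 ** log_ratio * pct_p * 1e4
            pct_c = max(rng.normal(config.c_mean, config.c_sd), 5.0)
            pct_n = max(
                rng.normal(config.n_base + config.n_offsets.get(region, 0.0), config.n_sd),
                0.05,
            )
            d15n = rng.normal(config.d15n_means.get(region, 0.0), config.d15n_sd)
            d0, d1 = (pd.Timestamp(d) for d in _ERA_DATES[era])
            date = d0 + pd.Timedelta(days=int(rng.integers(0, (d1 - d0).days + 1)))
            species = "S_fluitans_III" if rng.random() < 0.5 else "S_natans_I"
            cruise = ("A20" if lon > -60 else "A22") if era == "y2021" else "archive"
            counter += 1
            rows.append(dict(
                sample_id=f"SYN-{counter:04d}",
                cruise=cruise,
                station_id=f"{cruise}-{counter:03d}",
                latitude=round(lat, 4),
                longitude=round(lon, 4),
                date=date.date().isoformat(),
                species=species,
                replicate=int(rng.integers(1, 4)),
                pct_C=pct_c,
                pct_N=pct_n,
                pct_P=pct_p,
                d15N=d15n,
                as_ug_g=as_ug_g,
                era=era,
            ))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FieldGenConfig:
    """Analytic field specification.

    kind "uniform": constant (u0, v0).  kind "solid_body": rotation at
    angular rate omega (rad/s) about (center_lon, center_lat) on the local
    tangent plane.  kind "gyre": a single sinusoidal gyre cell of amplitude
    ``amplitude`` m/s over the domain (no closed-form trajectory).
    """

    kind: str = "uniform"
    lon_range: tuple[float, float] = (-80.0, -40.0)
    lat_range: tuple[float, float] = (0.0, 40.0)
    spacing: float = 1.0 / 3.0
    t_span: float = 90 * 86400.0
    t_step: float = 86400.0
    u0: float = 0.0
    v0: float = 0.0
    center_lon: float = -60.0
    center_lat: float = 20.0
    omega: float = 2 * np.pi / (30 * 86400.0)
    amplitude: float = 0.2
    steady: bool = True

    def __post_init__(self):
        if self.kind not in ("uniform", "solid_body", "gyre"):
            raise ConfigError(f"unknown field kind {self.kind!r}")
        if self.spacing <= 0:
            raise ConfigError("spacing must be positive")
        if self.kind == "gyre":
            # require the grid to resolve the cell: >= 8 nodes per wavelength
            width = min(
                self.lon_range[1] - self.lon_range[0],
                self.lat_range[1] - self.lat_range[0],
            )
            if width / self.spacing < 8:
                raise ConfigError(
                    "grid under-resolves the gyre: need >= 8 nodes per wavelength"
                )


def _gudermann_inv(phi_rad):
    return np.log(np.tan(np.pi / 4 + phi_rad / 2))


def gen_field(config: FieldGenConfig) -> tuple[GriddedField, Callable | None]:
    """Build an analytic :class:`GriddedField` and, where one exists, the
    exact trajectory evaluator ``traj(lon0, lat0, t_seconds) -> (lon, lat)``.

    The uniform evaluator solves the spherical kinematics exactly (constant
    u, v in m/s; longitude advances with the inverse Gudermannian of
    latitude when v != 0).  The solid-body evaluator rotates positions on
    the tangent plane at the rotation center — the same fixed-metric plane
    the field itself is defined on.
    """
    lon = np.arange(config.lon_range[0], config.lon_range[1] + 1e-9, config.spacing)
    lat = np.arange(config.lat_range[0], config.lat_range[1] + 1e-9, config.spacing)
    if config.steady:
        time = np.array([0.0])
    else:
        time = np.arange(0.0, config.t_span + 1e-6, config.t_step)
    LON, LAT = np.meshgrid(lon, lat)

    if config.kind == "uniform":
        u2d = np.full_like(LON, config.u0)
        v2d = np.full_like(LON, config.v0)

        def traj(lon0, lat0, t):
            # offsets computed in degrees so a zero field is exactly stationary
            t = np.asarray(t, dtype=float)
            phi0 = lat0 * _DEG
            phi = phi0 + config.v0 * t / R_EARTH
            if config.v0 == 0:
                dlam = config.u0 * t / (R_EARTH * np.cos(phi0))
            else:
                dlam = (config.u0 / config.v0) * (
                    _gudermann_inv(phi) - _gudermann_inv(phi0)
                )
            return lon0 + dlam / _DEG, lat0 + config.v0 * t / R_EARTH / _DEG

    elif config.kind == "solid_body":
        cosc = np.cos(config.center_lat * _DEG)
        x = R_EARTH * cosc * (LON - config.center_lon) * _DEG
        y = R_EARTH * (LAT - config.center_lat) * _DEG
        u2d = -config.omega * y
        v2d = config.omega * x

        def traj(lon0, lat0, t):
            t = np.asarray(t, dtype=float)
            x0 = R_EARTH * cosc * (lon0 - config.center_lon) * _DEG
            y0 = R_EARTH * (lat0 - config.center_lat) * _DEG
            c, s = np.cos(config.omega * t), np.sin(config.omega * t)
            xt = c * x0 - s * y0
            yt = s * x0 + c * y0
            return (
                config.center_lon + xt / (R_EARTH * cosc) / _DEG,
                config.center_lat + yt / R_EARTH / _DEG,
            )

    else:  # gyre: one sinusoidal streamfunction cell, no closed form
        fx = (LON - config.lon_range[0]) / (config.lon_range[1] - config.lon_range[0])
        fy = (LAT - config.lat_range[0]) / (config.lat_range[1] - config.lat_range[0])
        u2d = -config.amplitude * np.cos(np.pi * fy) * np.sin(np.pi * fx)
        v2d = config.amplitude * np.sin(np.pi * fy) * np.cos(np.pi * fx)
        traj = None

    u = np.broadcast_to(u2d, (time.size,) + u2d.shape).copy()
    v = np.broadcast_to(v2d, (time.size,) + v2d.shape).copy()
    field = GriddedField(lon=lon, lat=lat, time=time, u=u, v=v)
    return field, traj


def gen_stations(n: int, box: tuple[float, float, float, float], seed: int = 0,
                 release_time: float | None = None) -> pd.DataFrame:
    """Uniform random release sites in (lon_w, lon_e, lat_s, lat_n).

    Returns the station-list schema: station_id, longitude, latitude and
    (optionally) release_time in field seconds.
    """
    lon_w, lon_e, lat_s, lat_n = box
    if lon_e <= lon_w or lat_n <= lat_s:
        raise ConfigError("station box must have positive extent")
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "station_id": [f"ST{i:03d}" for i in range(n)],
        "longitude": rng.uniform(lon_w, lon_e, size=n),
        "latitude": rng.uniform(lat_s, lat_n, size=n),
    })
    if release_time is not None:
        frame["release_time"] = float(release_time)
    return frame
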