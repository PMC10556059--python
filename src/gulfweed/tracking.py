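"""Lagrangian particle tracking with windage and random-walk diffusion.

Particles released at sampling stations are advected by the surface-current
velocity plus a windage fraction of the 10-m wind, with an added random-walk
perturbation each time step representing unresolved eddy diffusion.  The
Gaussian step has total 2-D displacement variance sigma^2 = 4*D*dt (i.e.
per-component variance 2*D*dt) so that the ensemble mean squared
displacement grows as MSD = 4*D*t, the standard 2-D Fickian law; the
alternative reading (per-component variance 4*D*dt) is available as
``sigma_convention="per_component"``.  Defaults follow the source-water
reconstruction this tracker exists for: D = 4000 m^2/s, windage = 2%,
dt = 6 h, 60 days backward, 100 particles per station.

Backward mode negates the advective (current + windage) velocity and steps
earlier in time; the diffusion step is applied with the same magnitude in
both directions (a random walk is not time-reversible, so backtracking is a
statistical, not literal, inversion).

Meters convert to degrees on a local tangent plane each step:
dlat = dy / R_earth, dlon = dx / (R_earth * cos(lat)), R_earth = 6,371,000 m.

Particles whose velocity becomes undefined (off the grid or on a
fully-masked stencil) and particles landing on a masked grid cell are
deactivated ("beached") and frozen; deactivated particles never move again
and the particle count is conserved.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DomainError
from .fields import GriddedField

logger = logging.getLogger(__name__)

__all__ = [
    "R_EARTH",
    "BacktrackConfig",
    "TrajectoryEnsemble",
    "step_particle",
    "backtrack_ensemble",
    "ensemble_centroid",
    "estimate_diffusivity",
    "write_trajectories",
    "read_trajectories",
]

R_EARTH = 6_371_000.0  # m
_DEG = np.pi / 180.0


@dataclass(frozen=True)
class BacktrackConfig:
    """Tracker configuration.

    diffusivity
        Horizontal eddy diffusivity D in m^2/s (default 4000, an Argo-based
        regional estimate).
    windage
        Dimensionless fraction of the 10-m wind added to the current
        velocity (default 0.02; realistic Sargassum values span 0.5-3%).
    dt, duration
        Time step and total tracked time, seconds; duration must be a
        positive multiple of dt.  Defaults 6 h and 60 days.
    sigma_convention
        "total": per-component step SD sqrt(2*D*dt) so the 2-D displacement
        variance is 4*D*dt (MSD = 4*D*t).  "per_component": SD sqrt(4*D*dt).
    integrator
        "euler" (default; matches the random-walk time discretization) or
        "rk4" for the advective part.
    """

    diffusivity: float = 4000.0
    windage: float = 0.02
    dt: float = 6 * 3600.0
    duration: float = 60 * 86400.0
    n_particles: int = 100
    direction: str = "backward"
    seed: int = 0
    save_stride: int = 1
    integrator: str = "euler"
    sigma_convention: str = "total"

    def __post_init__(self):
        if self.diffusivity < 0:
            raise DomainError("diffusivity must be >= 0")
        if not 0.0 <= self.windage <= 0.1:
            raise DomainError("windage must lie in [0, 0.1]")
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        n_steps = self.duration / self.dt
        if self.duration <= 0 or abs(n_steps - round(n_steps)) > 1e-9:
            raise DomainError("duration must be a positive multiple of dt")
        if self.direction not in ("backward", "forward"):
            raise DomainError("direction must be 'backward' or 'forward'")
        if self.integrator not in ("euler", "rk4"):
            raise DomainError("integrator must be 'euler' or 'rk4'")
        if self.sigma_convention not in ("total", "per_component"):
            raise DomainError("sigma_convention must be 'total' or 'per_component'")
        if self.n_particles < 1 or self.save_stride < 1:
            raise DomainError("n_particles and save_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def step_sd(self) -> float:
        """Per-component Gaussian step SD in meters."""
        factor = 2.0 if self.sigma_convention == "total" else 4.0
        return float(np.sqrt(factor * self.diffusivity * self.dt))


@dataclass
class TrajectoryEnsemble:
    """Trajectories of one station's particle ensemble.

    ``lon``/``lat`` have shape (n_particles, n_saved); ``active`` marks
    particles still moving at each saved step (a deactivated particle stays
    frozen at its last position).  ``times`` are the saved physical times in
    field seconds (decreasing for backward runs).
    """

    station_id: str
    release_lon: float
    release_lat: float
    release_time: float
    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    active: np.ndarray
    config: BacktrackConfig
    deactivation_reason: list = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return self.lon.shape[0]

    def centroid(self):
        return ensemble_centroid(self)


def _meters_to_degrees(dx, dy, lat):
    coslat = np.cos(np.asarray(lat) * _DEG)
    if np.any(np.abs(coslat) < 1e-6):
        raise DomainError("particle too close to a pole for tangent-plane stepping")
    return dx / (R_EARTH * coslat) / _DEG, dy / R_EARTH / _DEG


def _sample_velocity(lon, lat, t, currents, winds, windage):
    u, v, _ = currents.interp(lon, lat, np.full_like(lon, t), out_of_bounds="nan")
    if winds is not None and windage > 0:
        uw, vw, _ = winds.interp(lon, lat, np.full_like(lon, t), out_of_bounds="nan")
        u = u + windage * uw
        v = v + windage * vw
    return u, v


def step_particle(
    lon,
    lat,
    t: float,
    currents: GriddedField,
    winds: GriddedField | None,
    config: BacktrackConfig,
    rng: np.random.Generator,
):
    """Advance particles one time step.

    Returns ``(new_lon, new_lat, new_t, alive, reason)`` where ``alive`` is
    False for particles whose velocity was undefined (left unmoved) or which
    landed on a masked cell (left at the landing point).  The Gaussian
    perturbation is drawn for every particle each call, so random streams do
    not depend on which particles happen to be active.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    sign = -1.0 if config.direction == "backward" else 1.0
    dt = config.dt

    def advective(lo, la, tt):
        u, v = _sample_velocity(lo, la, tt, currents, winds, config.windage)
        return sign * u, sign * v

    if config.integrator == "euler":
        du, dv = advective(lon, lat, t)
        dx, dy = du * dt, dv * dt
    else:  # rk4 on the advective part
        u1, v1 = advective(lon, lat, t)
        dlo, dla = _meters_to_degrees(u1 * dt / 2, v1 * dt / 2, lat)
        u2, v2 = advective(lon + dlo, lat + dla, t + sign * dt / 2)
        dlo, dla = _meters_to_degrees(u2 * dt / 2, v2 * dt / 2, lat)
        u3, v3 = advective(lon + dlo, lat + dla, t + sign * dt / 2)
        dlo, dla = _meters_to_degrees(u3 * dt, v3 * dt, lat)
        u4, v4 = advective(lon + dlo, lat + dla, t + sign * dt)
        dx = dt * (u1 + 2 * u2 + 2 * u3 + u4) / 6.0
        dy = dt * (v1 + 2 * v2 + 2 * v3 + v4) / 6.0

    noise = rng.normal(0.0, config.step_sd, size=(lon.size, 2))
    dx = dx + noise[:, 0]
    dy = dy + noise[:, 1]

    lost = ~np.isfinite(dx) | ~np.isfinite(dy)
    dlon, dlat = _meters_to_degrees(np.where(lost, 0.0, dx), np.where(lost, 0.0, dy), lat)
    new_lon = lon + dlon
    new_lat = lat + dlat
    new_t = t + sign * dt

    in_domain = currents.contains(new_lon, new_lat)
    beached = in_domain & currents.cell_masked(new_lon, new_lat) & ~lost
    out = ~in_domain & ~lost
    # lost / out-of-domain particles stay put; beached ones keep the landing point
    new_lon = np.where(lost | out, lon, new_lon)
    new_lat = np.where(lost | out, lat, new_lat)
    alive = ~(lost | out | beached)
    reason = np.where(lost, "lost", np.where(out, "out_of_domain",
                      np.where(beached, "beached", "")))
    return new_lon, new_lat, new_t, alive, reason


def backtrack_ensemble(
    stations,
    currents: GriddedField,
    winds: GriddedField | None,
    config: BacktrackConfig,
) -> list[TrajectoryEnsemble]:
    """Track an ensemble of particles from each release station.

    ``stations`` is a DataFrame with columns ``station_id``, ``longitude``,
    ``latitude`` and optionally ``release_time`` (field seconds; defaults to
    the last field time for backward runs, the first for forward).  Stations
    outside the field domain at release time are skipped with a log entry.
    Identical (config, seed) reruns are bit-identical: each station's RNG
    stream is derived from (seed, station index).
    """
    if config.windage > 0 and winds is None:
        raise DomainError("windage > 0 requires a wind field")
    ensembles = []
    for idx, st in stations.reset_index(drop=True).iterrows():
        lon0, lat0 = float(st["longitude"]), float(st["latitude"])
        if "release_time" in st and pd.notna(st.get("release_time")):
            t0 = float(st["release_time"])
        elif config.direction == "backward":
            t0 = float(currents.time[-1])
        else:
            t0 = float(currents.time[0])
        if not bool(currents.contains(lon0, lat0, t0)):
            logger.warning(
                "station %s at (%.3f, %.3f) outside field domain; skipped",
                st.get("station_id", idx), lon0, lat0,
            )
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(int(idx),))
        )
        n = config.n_particles
        lon = np.full(n, lon0)
        lat = np.full(n, lat0)
        alive = np.ones(n, dtype=bool)
        reasons = np.full(n, "", dtype=object)
        t = t0
        saved_steps = list(range(0, config.n_steps + 1, config.save_stride))
        if saved_steps[-1] != config.n_steps:
            saved_steps.append(config.n_steps)
        n_saved = len(saved_steps)
        lons = np.empty((n, n_saved))
        lats = np.empty((n, n_saved))
        act = np.empty((n, n_saved), dtype=bool)
        times = np.empty(n_saved)
        save_i = 0
        lons[:, 0], lats[:, 0], act[:, 0], times[0] = lon, lat, alive, t
        save_i = 1
        for step in range(1, config.n_steps + 1):
            new_lon, new_lat, t_next, step_alive, step_reason = step_particle(
                lon, lat, t, currents, winds, config, rng
            )
            moved = alive  # only previously-active particles move
            lon = np.where(moved, new_lon, lon)
            lat = np.where(moved, new_lat, lat)
            newly_dead = moved & ~step_alive
            reasons[newly_dead] = step_reason[newly_dead]
            alive = alive & step_alive
            t = t_next
            if save_i < n_saved and step == saved_steps[save_i]:
                lons[:, save_i], lats[:, save_i] = lon, lat
                act[:, save_i] = alive
                times[save_i] = t
                save_i += 1
        ensembles.append(
            TrajectoryEnsemble(
                station_id=str(st.get("station_id", idx)),
                release_lon=lon0, release_lat=lat0, release_time=t0,
                times=times, lon=lons, lat=lats, active=act, config=config,
                deactivation_reason=[
                    (int(i), str(r)) for i, r in enumerate(reasons) if r
                ],
            )
        )
    return ensembles


def _circular_mean_lon(lons_deg: np.ndarray) -> float:
    th = lons_deg * _DEG
    ang = np.arctan2(np.sin(th).mean(), np.cos(th).mean()) / _DEG
    return float((ang + 180.0) % 360.0 - 180.0)


def ensemble_centroid(ensemble: TrajectoryEnsemble):
    """Per-step mean position of the still-active particles.

    Longitudes are averaged circularly (unwrapped about the ensemble mean),
    so ensembles straddling the dateline average to ~180 deg rather than 0.
    Once a particle deactivates it is excluded from later means; if every
    particle is inactive the centroid path is truncated at that step.
    Returns ``(times, lon_c, lat_c, n_active)`` arrays.
    """
    n_saved = ensemble.times.size
    lon_c, lat_c, n_act, times = [], [], [], []
    for kk in range(n_saved):
        act = ensemble.active[:, kk]
        # particles active at release contribute at step 0 even if they die on step 1
        if kk == 0:
            act = np.ones(ensemble.n_particles, dtype=bool)
        if not act.any():
            break
        lon_c.append(_circular_mean_lon(ensemble.lon[act, kk]))
        lat_c.append(float(ensemble.lat[act, kk].mean()))
        n_act.append(int(act.sum()))
        times.append(ensemble.times[kk])
    return (np.array(times), np.array(lon_c), np.array(lat_c), np.array(n_act))


def estimate_diffusivity(ensemble: TrajectoryEnsemble, method: str = "msd") -> float:
    """Estimate horizontal diffusivity from a quiescent-field ensemble.

    "msd": average over saved steps of (ensemble mean squared displacement
    from the release point) / (4 * elapsed time) — the 2-D Fickian estimator.
    "increments": the same quantity built from per-step displacement
    increments, MSD_step / (4 * dt_saved); a cross-check that should agree
    within Monte-Carlo error.  Displacements are converted to meters on a
    tangent plane at the release point.
    """
    if ensemble.n_particles < 10:
        warnings.warn(
            "fewer than 10 particles: diffusivity estimate will have wide variance",
            stacklevel=2,
        )
    lat0 = ensemble.release_lat
    x = (ensemble.lon - ensemble.release_lon) * _DEG * R_EARTH * np.cos(lat0 * _DEG)
    y = (ensemble.lat - ensemble.release_lat) * _DEG * R_EARTH
    tau = np.abs(ensemble.times - ensemble.times[0])
    if method == "msd":
        msd = (x**2 + y**2).mean(axis=0)
        sel = tau > 0
        if not sel.any():
            return 0.0
        return float(np.mean(msd[sel] / (4.0 * tau[sel])))
    if method == "increments":
        dx = np.diff(x, axis=1)
        dy = np.diff(y, axis=1)
        dtau = np.diff(tau)
        msd = (dx**2 + dy**2).mean(axis=0)
        return float(np.mean(msd / (4.0 * dtau)))
    raise ValueError("method must be 'msd' or 'increments'")


# ----------------------------------------------------------------------
# trajectory I/O
# ----------------------------------------------------------------------

def _config_json(config: BacktrackConfig) -> str:
    return json.dumps(asdict(config), sort_keys=True)


def write_trajectories(ensembles, path, format: str = "netcdf") -> None:
    """Write trajectory ensembles to netCDF, long-format CSV, or GeoJSON.

    netCDF and CSV round-trip losslessly (positions, active flags, config
    and seed) via :func:`read_trajectories`.  GeoJSON carries one LineString
    per particle plus one centroid LineString per station.
    """
    path = Path(path)
    ensembles = list(ensembles)
    if format == "netcdf":
        shapes = {e.lon.shape for e in ensembles}
        if len(shapes) != 1:
            raise ValueError("netCDF output requires equally-shaped ensembles")
        ds = xr.Dataset(
            {
                "lon": (("station", "particle", "step"), np.stack([e.lon for e in ensembles])),
                "lat": (("station", "particle", "step"), np.stack([e.lat for e in ensembles])),
                "active": (
                    ("station", "particle", "step"),
                    np.stack([e.active for e in ensembles]).astype(np.int8),
                ),
                "time": (("station", "step"), np.stack([e.times for e in ensembles])),
                "release_lon": (("station",), [e.release_lon for e in ensembles]),
                "release_lat": (("station",), [e.release_lat for e in ensembles]),
                "release_time": (("station",), [e.release_time for e in ensembles]),
            },
            attrs={
                "config": _config_json(ensembles[0].config),
                "station_ids": json.dumps([e.station_id for e in ensembles]),
            },
        )
        ds.to_netcdf(path, engine="scipy")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# config: {_config_json(ensembles[0].config)}\n")
            w = csv.writer(fh)
            w.writerow(["station_id", "particle", "step", "time", "lon", "lat", "active"])
            for e in ensembles:
                for p in range(e.n_particles):
                    for kk in range(e.times.size):
                        w.writerow([
                            e.station_id, p, kk, repr(float(e.times[kk])),
                            repr(float(e.lon[p, kk])), repr(float(e.lat[p, kk])),
                            int(e.active[p, kk]),
                        ])
    elif format == "geojson":
        features = []
        for e in ensembles:
            for p in range(e.n_particles):
                features.append({
                    "type": "Feature",
                    "properties": {"station_id": e.station_id, "particle": p, "kind": "trajectory"},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [
                            [float(e.lon[p, kk]), float(e.lat[p, kk])]
                            for kk in range(e.times.size)
                        ],
                    },
                })
            _, clon, clat, _n = ensemble_centroid(e)
            features.append({
                "type": "Feature",
                "properties": {"station_id": e.station_id, "kind": "centroid"},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(a), float(b)] for a, b in zip(clon, clat)],
                },
            })
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


def read_trajectories(path, format: str = "netcdf") -> list[TrajectoryEnsemble]:
    """Inverse of :func:`write_trajectories` for netCDF and CSV."""
    path = Path(path)
    if format == "netcdf":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            config = BacktrackConfig(**json.loads(ds.attrs["config"]))
            ids = json.loads(ds.attrs["station_ids"])
            out = []
            for s, sid in enumerate(ids):
                out.append(TrajectoryEnsemble(
                    station_id=sid,
                    release_lon=float(ds["release_lon"][s]),
                    release_lat=float(ds["release_lat"][s]),
                    release_time=float(ds["release_time"][s]),
                    times=np.asarray(ds["time"][s].values, dtype=float),
                    lon=np.asarray(ds["lon"][s].values, dtype=float),
                    lat=np.asarray(ds["lat"][s].values, dtype=float),
                    active=np.asarray(ds["active"][s].values, dtype=bool),
                    config=config,
                ))
        return out
    if format == "csv":
        with open(path) as fh:
            header = fh.readline()
            config = BacktrackConfig(**json.loads(header.split("# config:", 1)[1]))
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        out = []
        for sid, sub in frame.groupby("station_id", sort=False):
            npart = int(sub["particle"].max()) + 1
            nstep = int(sub["step"].max()) + 1
            lon = np.empty((npart, nstep))
            lat = np.empty((npart, nstep))
            active = np.empty((npart, nstep), dtype=bool)
            times = np.empty(nstep)
            for row in sub.itertuples():
                lon[row.particle, row.step] = row.lon
                lat[row.particle, row.step] = row.lat
                active[row.particle, row.step] = bool(row.active)
                times[row.step] = row.time
            out.append(TrajectoryEnsemble(
                station_id=str(sid),
                release_lon=float(lon[0, 0]), release_lat=float(lat[0, 0]),
                release_time=float(times[0]),
                times=times, lon=lon, lat=lat, active=active, config=config,
            ))
        return out
    raise ValueError(f"unsupported trajectory format {format!r}")
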