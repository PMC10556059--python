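"""Particle stepping, ensembles, diffusivity recovery, centroids, I/O."""

import json

import numpy as np
import pandas as pd
import pytest

from gulfweed import (
    BacktrackConfig,
    DomainError,
    FieldGenConfig,
    GriddedField,
    TrajectoryEnsemble,
    backtrack_ensemble,
    ensemble_centroid,
    estimate_diffusivity,
    gen_field,
    read_trajectories,
    step_particle,
    write_trajectories,
)
from gulfweed.tracking import R_EARTH

M_PER_DEG = R_EARTH * np.pi / 180.0


def _station(lon=-60.0, lat=20.0, t=0.0, sid="S1"):
    return pd.DataFrame(
        {"station_id": [sid], "longitude": [lon], "latitude": [lat], "release_time": [t]}
    )


class TestStepParticle:
    def test_eastward_current_at_equator(self):
        field, _ = gen_field(FieldGenConfig(kind="uniform", u0=1.0, lat_range=(-5.0, 5.0)))
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, dt=3600.0,
                              duration=3600.0, n_particles=1, direction="forward")
        rng = np.random.default_rng(0)
        lon, lat, _, alive, _ = step_particle([-60.0], [0.0], 0.0, field, None, cfg, rng)
        assert lat[0] == 0.0
        assert lon[0] - (-60.0) == pytest.approx(3600.0 / M_PER_DEG, rel=1e-12)
        assert alive[0]

    def test_two_percent_windage_displacement(self):
        currents, _ = gen_field(FieldGenConfig(kind="uniform", u0=0.0, v0=0.0))
        winds, _ = gen_field(FieldGenConfig(kind="uniform", u0=0.0, v0=10.0))
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.02, dt=3600.0,
                              duration=3600.0, n_particles=1, direction="forward")
        rng = np.random.default_rng(0)
        lon, lat, _, _, _ = step_particle([-60.0], [20.0], 0.0, currents, winds, cfg, rng)
        dy_m = (lat[0] - 20.0) * M_PER_DEG
        assert dy_m == pytest.approx(720.0, abs=1e-9)  # 0.02 * 10 m/s * 3600 s
        assert lon[0] == -60.0

    def test_diffusion_only_step_statistics(self, quiescent_field):
        cfg = BacktrackConfig(diffusivity=4000.0, windage=0.0, dt=21600.0,
                              duration=21600.0, n_particles=1, direction="forward")
        rng = np.random.default_rng(2)
        n = 20_000
        lon, lat, _, _, _ = step_particle(
            np.full(n, -60.0), np.full(n, 20.0), 0.0, quiescent_field, None, cfg, rng
        )
        dx = (lon + 60.0) * M_PER_DEG * np.cos(np.radians(20.0))
        dy = (lat - 20.0) * M_PER_DEG
        var_2d = (dx**2 + dy**2).mean()
        expected = 4 * 4000.0 * 21600.0
        assert abs(dx.mean()) < 3 * np.sqrt(expected / 2 / n) * 1.2
        assert var_2d == pytest.approx(expected, rel=0.05)

    def test_per_component_convention_doubles_variance(self, quiescent_field):
        base = BacktrackConfig(diffusivity=4000.0, dt=21600.0, duration=21600.0)
        alt = BacktrackConfig(diffusivity=4000.0, dt=21600.0, duration=21600.0,
                              sigma_convention="per_component")
        assert alt.step_sd**2 == pytest.approx(2 * base.step_sd**2)


class TestEnsembles:
    def test_null_dynamics_stay_put(self, quiescent_field, one_station):
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, n_particles=5,
                              direction="backward")
        ens = backtrack_ensemble(one_station, quiescent_field, None, cfg)[0]
        assert np.all(ens.lon == -60.0) and np.all(ens.lat == 20.0)
        assert ens.active.all()
        assert ens.times[-1] == pytest.approx(-60 * 86400.0)

    def test_solid_body_angular_displacement_euler(self):
        omega = 2 * np.pi / (30 * 86400.0)
        fc = FieldGenConfig(kind="solid_body", center_lon=-60.0, center_lat=8.0,
                            omega=omega, lat_range=(0.0, 16.0), spacing=0.25)
        field, _ = gen_field(fc)
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, dt=6 * 3600.0,
                              duration=30 * 86400.0, n_particles=1,
                              direction="forward", integrator="euler")
        ens = backtrack_ensemble(_station(-59.0, 8.0), field, None, cfg)[0]
        x = (ens.lon[0] + 60.0) * np.cos(np.radians(8.0))
        y = ens.lat[0] - 8.0
        theta = np.unwrap(np.arctan2(y, x))
        total = theta[-1] - theta[0]
        assert abs(total - omega * 30 * 86400.0) / (2 * np.pi) < 0.005

    def test_integrator_accuracy_hierarchy(self):
        # Euler error roughly halves with dt (order >= 1); RK4 is orders of
        # magnitude closer to the closed-form orbit at the same step
        omega = 2 * np.pi / (30 * 86400.0)
        fc = FieldGenConfig(kind="solid_body", center_lon=-60.0, center_lat=0.0,
                            omega=omega, lat_range=(-8.0, 8.0), spacing=0.25)
        field, traj = gen_field(fc)

        def end_error(dt, integrator):
            cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, dt=dt,
                                  duration=30 * 86400.0, n_particles=1,
                                  direction="forward", integrator=integrator)
            ens = backtrack_ensemble(_station(-59.0, 0.0), field, None, cfg)[0]
            elon, elat = traj(-59.0, 0.0, ens.times[-1] - ens.times[0])
            return np.hypot(ens.lon[0, -1] - elon, ens.lat[0, -1] - elat)

        e_coarse = end_error(6 * 3600.0, "euler")
        e_fine = end_error(3 * 3600.0, "euler")
        assert 1.5 < e_coarse / e_fine < 3.0
        assert end_error(6 * 3600.0, "rk4") < e_coarse / 100.0

    def test_forward_backward_reversibility(self):
        omega = 2 * np.pi / (30 * 86400.0)
        fc = FieldGenConfig(kind="solid_body", center_lon=-60.0, center_lat=8.0,
                            omega=omega, lat_range=(0.0, 16.0), spacing=0.25)
        field, _ = gen_field(fc)
        fwd_cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, dt=6 * 3600.0,
                                  duration=20 * 86400.0, n_particles=1,
                                  direction="forward", integrator="rk4")
        fwd = backtrack_ensemble(_station(-59.0, 8.0), field, None, fwd_cfg)[0]
        end = _station(float(fwd.lon[0, -1]), float(fwd.lat[0, -1]),
                       t=float(fwd.times[-1]))
        bwd_cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, dt=6 * 3600.0,
                                  duration=20 * 86400.0, n_particles=1,
                                  direction="backward", integrator="rk4")
        bwd = backtrack_ensemble(end, field, None, bwd_cfg)[0]
        err_m = np.hypot(
            (bwd.lon[0, -1] + 59.0) * np.cos(np.radians(8.0)), bwd.lat[0, -1] - 8.0
        ) * M_PER_DEG
        assert err_m < 100.0

    def test_windage_linearity(self, quiescent_field, one_station):
        winds, _ = gen_field(FieldGenConfig(kind="uniform", u0=5.0, v0=-3.0))

        def drift(w):
            cfg = BacktrackConfig(diffusivity=0.0, windage=w, dt=6 * 3600.0,
                                  duration=5 * 86400.0, n_particles=1,
                                  direction="forward")
            e = backtrack_ensemble(one_station, quiescent_field, winds, cfg)[0]
            return e.lon[0, -1] - e.lon[0, 0], e.lat[0, -1] - e.lat[0, 0]

        d1, d2 = drift(0.01), drift(0.02)
        assert d2[1] == pytest.approx(2 * d1[1], rel=1e-9)

    def test_bit_identical_reruns(self, quiescent_field, one_station):
        cfg = BacktrackConfig(diffusivity=4000.0, windage=0.0, n_particles=20,
                              duration=10 * 86400.0, seed=9)
        a = backtrack_ensemble(one_station, quiescent_field, None, cfg)[0]
        b = backtrack_ensemble(one_station, quiescent_field, None, cfg)[0]
        assert np.array_equal(a.lon, b.lon) and np.array_equal(a.lat, b.lat)

    def test_station_outside_domain_skipped(self, quiescent_field):
        stations = pd.concat([_station(), _station(lon=100.0, sid="BAD")],
                             ignore_index=True)
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, n_particles=2,
                              duration=86400.0 * 1, dt=6 * 3600.0)
        out = backtrack_ensemble(stations, quiescent_field, None, cfg)
        assert [e.station_id for e in out] == ["S1"]

    def test_beached_particles_freeze_and_count_conserved(self):
        lon = np.arange(-62.0, -56.9, 0.5)
        lat = np.arange(18.0, 22.1, 0.5)
        mask = np.zeros((lat.size, lon.size), dtype=bool)
        mask[:, lon > -59.0] = True  # "coast" on the east
        nt = 1
        u = np.full((nt, lat.size, lon.size), 0.5)
        u[:, :, mask[0]] = np.nan
        field = GriddedField(lon=lon, lat=lat, time=[0.0], u=u,
                             v=np.zeros_like(u), mask=mask)
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, dt=6 * 3600.0,
                              duration=10 * 86400.0, n_particles=4,
                              direction="forward")
        ens = backtrack_ensemble(_station(-61.5, 20.0), field, None, cfg)[0]
        assert ens.n_particles == 4
        assert not ens.active[:, -1].any()
        assert {r for _, r in ens.deactivation_reason} <= {"beached", "lost"}
        # frozen after deactivation: final two saved positions identical
        assert np.array_equal(ens.lon[:, -1], ens.lon[:, -2])

    def test_windage_without_winds_rejected(self, quiescent_field, one_station):
        cfg = BacktrackConfig(windage=0.02, n_particles=1)
        with pytest.raises(DomainError):
            backtrack_ensemble(one_station, quiescent_field, None, cfg)


class TestDiffusivity:
    def test_recovery_and_linear_msd(self, quiescent_field, one_station):
        cfg = BacktrackConfig(diffusivity=4000.0, windage=0.0, dt=6 * 3600.0,
                              duration=30 * 86400.0, n_particles=1000,
                              direction="forward", seed=1)
        ens = backtrack_ensemble(one_station, quiescent_field, None, cfg)[0]
        d_hat = estimate_diffusivity(ens)
        assert d_hat == pytest.approx(4000.0, rel=0.10)
        # MSD grows linearly: regression R^2 > 0.99
        x = (ens.lon + 60.0) * M_PER_DEG * np.cos(np.radians(20.0))
        y = (ens.lat - 20.0) * M_PER_DEG
        msd = (x**2 + y**2).mean(axis=0)
        tau = np.abs(ens.times - ens.times[0])
        r = np.corrcoef(tau, msd)[0, 1]
        assert r**2 > 0.99
        # cross-check estimator built from per-step increments
        d_inc = estimate_diffusivity(ens, method="increments")
        assert d_inc == pytest.approx(d_hat, rel=0.10)

    def test_zero_diffusivity(self, quiescent_field, one_station):
        cfg = BacktrackConfig(diffusivity=0.0, windage=0.0, n_particles=12,
                              duration=5 * 86400.0, direction="forward")
        ens = backtrack_ensemble(one_station, quiescent_field, None, cfg)[0]
        assert estimate_diffusivity(ens) == 0.0

    def test_few_particles_warns(self, quiescent_field, one_station):
        cfg = BacktrackConfig(diffusivity=100.0, windage=0.0, n_particles=5,
                              duration=5 * 86400.0, direction="forward")
        ens = backtrack_ensemble(one_station, quiescent_field, None, cfg)[0]
        with pytest.warns(UserWarning, match="wide variance"):
            estimate_diffusivity(ens)


def _manual_ensemble(lon, lat, active=None):
    lon = np.asarray(lon, dtype=float)
    cfg = BacktrackConfig(n_particles=lon.shape[0])
    return TrajectoryEnsemble(
        station_id="M", release_lon=float(lon[0, 0]), release_lat=float(lat[0][0]),
        release_time=0.0, times=np.arange(lon.shape[1], dtype=float),
        lon=lon, lat=np.asarray(lat, dtype=float),
        active=np.ones(lon.shape, dtype=bool) if active is None else active,
        config=cfg,
    )


class TestCentroid:
    def test_identical_particles(self):
        ens = _manual_ensemble([[0.0, 1.0], [0.0, 1.0]], [[5.0, 6.0], [5.0, 6.0]])
        _, clon, clat, _ = ensemble_centroid(ens)
        assert np.allclose(clon, [0.0, 1.0]) and np.allclose(clat, [5.0, 6.0])

    def test_symmetric_pair_averages_to_center(self):
        ens = _manual_ensemble([[-1.0], [1.0]], [[10.0], [20.0]])
        _, clon, clat, _ = ensemble_centroid(ens)
        assert clon[0] == pytest.approx(0.0, abs=1e-12)
        assert clat[0] == pytest.approx(15.0)

    def test_dateline_straddling_averages_to_180(self):
        ens = _manual_ensemble([[179.5], [-179.5]], [[0.0], [0.0]])
        _, clon, _, _ = ensemble_centroid(ens)
        assert abs(clon[0]) == pytest.approx(180.0, abs=1e-9)

    def test_inactive_excluded_and_truncation(self):
        active = np.array([[True, True, False], [True, False, False]])
        ens = _manual_ensemble(
            [[0.0, 1.0, 1.0], [10.0, 10.0, 10.0]],
            [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            active=active,
        )
        times, clon, _, n_act = ensemble_centroid(ens)
        assert len(times) == 2  # truncated where no particle remains active
        assert clon[1] == pytest.approx(1.0)  # second step: only particle 0
        assert list(n_act) == [2, 1]


class TestTrajectoryIO:
    @pytest.fixture()
    def small_ensembles(self, quiescent_field):
        st = pd.DataFrame({
            "station_id": ["A", "B"], "longitude": [-60.0, -58.0],
            "latitude": [20.0, 22.0], "release_time": [0.0, 0.0],
        })
        cfg = BacktrackConfig(diffusivity=500.0, windage=0.0, dt=6 * 3600.0,
                              duration=2 * 86400.0, n_particles=3, seed=4,
                              direction="forward")
        return backtrack_ensemble(st, quiescent_field, None, cfg)

    @pytest.mark.parametrize("fmt,ext", [("netcdf", "nc"), ("csv", "csv")])
    def test_lossless_round_trip(self, small_ensembles, tmp_path, fmt, ext):
        path = tmp_path / f"traj.{ext}"
        write_trajectories(small_ensembles, path, format=fmt)
        back = read_trajectories(path, format=fmt)
        for a, b in zip(small_ensembles, back):
            assert np.array_equal(a.lon, b.lon)
            assert np.array_equal(a.lat, b.lat)
            assert np.array_equal(a.active, b.active)
            assert a.config == b.config  # includes the seed

    def test_geojson_structure(self, small_ensembles, tmp_path):
        path = tmp_path / "traj.geojson"
        write_trajectories(small_ensembles, path, format="geojson")
        doc = json.loads(path.read_text())
        kinds = [f["properties"]["kind"] for f in doc["features"]]
        assert kinds.count("trajectory") == 2 * 3  # stations x particles
        assert kinds.count("centroid") == 2
        assert all(f["geometry"]["type"] == "LineString" for f in doc["features"])

    def test_csv_row_count(self, small_ensembles, tmp_path):
        path = tmp_path / "traj.csv"
        write_trajectories(small_ensembles, path, format="csv")
        frame = pd.read_csv(path, comment="#")
        n_saved = small_ensembles[0].times.size
        assert len(frame) == 2 * 3 * n_saved

    def test_unsupported_format(self, small_ensembles, tmp_path):
        with pytest.raises(ValueError):
            write_trajectories(small_ensembles, tmp_path / "x.foo", format="foo")
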