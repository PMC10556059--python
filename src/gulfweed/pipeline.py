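"""End-to-end orchestration: read/generate inputs, group and summarize
tissue chemistry, fit the As:P power law, run the correlation and isotope
calculations, backtrack source waters, and write a manifest.

Every run is driven by a :class:`RunConfig` (loadable from YAML); every
output file is listed in a manifest JSON with its SHA-256 hash, the package
version and every seed used, so a rerun with the same config reproduces the
hashes exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .fields import read_gridded_field
from .isotopes import IsotopeMixingParams, isotope_mixing
from .powerlaw import correlation_summary, fit_power_law
from .regions import RegionScheme, assign_regions, default_region_scheme
from .synthetic import (
    FieldGenConfig,
    TissueGenConfig,
    gen_field,
    gen_stations,
    gen_tissue_dataset,
)
from .tissue import add_ratio_columns, compare_groups, read_tissue_table, summarize_by_group
from .tracking import BacktrackConfig, backtrack_ensemble, ensemble_centroid, write_trajectories

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


def _one_of(name: str, spec: dict | None, keys=("path", "synthetic")):
    if spec is None:
        return None
    given = [k for k in keys if k in spec]
    if len(given) != 1:
        raise ConfigError(
            f"input {name!r} must specify exactly one of {keys}; got {given or 'none'}"
        )
    return given[0]


@dataclass
class RunConfig:
    """Full-run configuration.

    Each input block is either ``{"path": ...}`` (a real file) or
    ``{"synthetic": {...}}`` (a generator config) — never both.  ``seed``
    is the master seed; per-stage seeds derive from it deterministically.
    """

    outdir: str = "gulfweed_out"
    seed: int = 42
    tissue: dict = field(default_factory=lambda: {"synthetic": {}})
    currents: dict | None = None
    winds: dict | None = None
    stations: dict | None = None
    region_scheme: str | None = None
    fit: dict = field(default_factory=lambda: {"basis": "weight", "n_boot": 10_000})
    backtrack: dict = field(default_factory=dict)
    mixing: dict | None = None

    def __post_init__(self):
        for name in ("tissue", "currents", "winds", "stations"):
            _one_of(name, getattr(self, name))
        bt = dict(self.backtrack)
        windage = bt.get("windage", BacktrackConfig().windage)
        if self.currents is not None and self.stations is not None:
            if windage > 0 and self.winds is None:
                raise ConfigError(
                    "backtracking with windage > 0 requires a wind field; "
                    "provide 'winds' or set backtrack.windage to 0"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_field(spec: dict, outdir: Path, name: str):
    """Returns (field, written_path_or_None); synthetic fields are persisted."""
    kind = _one_of(name, spec)
    if kind == "path":
        return read_gridded_field(spec["path"], spec.get("variable_map")), None
    cfg = FieldGenConfig(**spec["synthetic"])
    fld, _ = gen_field(cfg)
    path = outdir / f"{name}.nc"
    fld.to_netcdf(path)
    return fld, path


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; return (and write) the run manifest.

    Stage failures re-raise as :class:`StageError` carrying the stage name;
    outputs written before the failure are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    def emit(path: Path):
        outputs.append(path)

    stage = "tissue"
    try:
        kind = _one_of("tissue", config.tissue)
        if kind == "synthetic":
            gen_cfg = TissueGenConfig(**{"seed": config.seed, **config.tissue["synthetic"]})
            frame = gen_tissue_dataset(gen_cfg)
            tissue_csv = outdir / "tissue_synthetic.csv"
            frame.to_csv(tissue_csv, index=False)
            emit(tissue_csv)
            table = read_tissue_table(tissue_csv)
        else:
            table = read_tissue_table(config.tissue["path"])
        manifest["stages"].append({"stage": stage, "n_accepted": table.n_accepted,
                                   "n_rejected": table.n_rejected})

        stage = "regions"
        scheme = (
            RegionScheme.from_yaml(config.region_scheme)
            if config.region_scheme
            else default_region_scheme()
        )
        frame = assign_regions(table.frame, scheme)
        frame = add_ratio_columns(frame, basis=config.fit.get("basis", "weight"))
        enriched_csv = outdir / "tissue_enriched.csv"
        frame.to_csv(enriched_csv, index=False)
        emit(enriched_csv)
        manifest["stages"].append({"stage": stage, "scheme": "default" if not config.region_scheme else config.region_scheme})

        stage = "summaries"
        summary = summarize_by_group(frame, ("region",))
        summary_csv = outdir / "summary_by_region.csv"
        summary.to_csv(summary_csv, index=False)
        emit(summary_csv)
        comparisons = {}
        for var in ("pct_N", "pct_P"):
            cmp = compare_groups(frame, var, "region")
            comparisons[var] = {
                "testable": cmp.testable,
                "method": cmp.method,
                "statistic": None if pd.isna(cmp.statistic) else cmp.statistic,
                "p_value": None if pd.isna(cmp.p_value) else cmp.p_value,
                "pairwise": None if cmp.pairwise is None else cmp.pairwise.to_dict("records"),
                "reason": cmp.reason,
            }
        cmp_json = outdir / "group_comparisons.json"
        cmp_json.write_text(json.dumps(comparisons, indent=2))
        emit(cmp_json)
        manifest["stages"].append({"stage": stage})

        stage = "asp_fit"
        sub = frame.dropna(subset=["pct_P", "as_to_p"])
        fit = fit_power_law(
            sub["pct_P"], sub["as_to_p"],
            n_boot=int(config.fit.get("n_boot", 10_000)),
            seed=config.seed,
        )
        fit_json = outdir / "asp_fit.json"
        doc = fit.to_dict()
        doc["basis"] = config.fit.get("basis", "weight")
        fit_json.write_text(json.dumps(doc, indent=2))
        emit(fit_json)
        manifest["stages"].append({"stage": stage, "slope": fit.slope, "n": fit.n})

        stage = "correlations"
        corr = correlation_summary(frame, seed=config.seed)
        corr_json = outdir / "correlations.json"
        corr_json.write_text(json.dumps({
            "correlations": corr.correlations.to_dict("records"),
            "ratio_fits": {
                k: (None if f is None else f.to_dict()) for k, f in corr.ratio_fits.items()
            },
        }, indent=2))
        emit(corr_json)
        manifest["stages"].append({"stage": stage})

        if config.mixing is not None:
            stage = "isotope_mixing"
            res = isotope_mixing(IsotopeMixingParams(**config.mixing))
            mix_json = outdir / "isotope_mixing.json"
            mix_json.write_text(json.dumps({
                "growth_factor": res.growth_factor, "doublings": res.doublings,
                **config.mixing,
            }, indent=2))
            emit(mix_json)
            manifest["stages"].append({"stage": stage, "doublings": res.doublings})

        if config.currents is not None and config.stations is not None:
            stage = "backtrack"
            currents, cur_path = _load_field(config.currents, outdir, "currents")
            if cur_path:
                emit(cur_path)
            winds = None
            if config.winds:
                winds, wnd_path = _load_field(config.winds, outdir, "winds")
                if wnd_path:
                    emit(wnd_path)
            skind = _one_of("stations", config.stations)
            if skind == "synthetic":
                scfg = dict(config.stations["synthetic"])
                stations = gen_stations(
                    scfg.get("n", 5), tuple(scfg.get("box", (-70, -52, 8, 38))),
                    seed=scfg.get("seed", config.seed),
                    release_time=scfg.get("release_time"),
                )
                st_csv = outdir / "stations.csv"
                stations.to_csv(st_csv, index=False)
                emit(st_csv)
            else:
                stations = pd.read_csv(config.stations["path"])
            bt_cfg = BacktrackConfig(**{"seed": config.seed, **config.backtrack})
            ensembles = backtrack_ensemble(stations, currents, winds, bt_cfg)
            traj_nc = outdir / "trajectories.nc"
            write_trajectories(ensembles, traj_nc, format="netcdf")
            emit(traj_nc)
            cent_rows = []
            for e in ensembles:
                times, clon, clat, nact = ensemble_centroid(e)
                for tt, lo, la, na in zip(times, clon, clat, nact):
                    cent_rows.append(dict(station_id=e.station_id, time=tt,
                                          lon=lo, lat=la, n_active=na))
            cent_csv = outdir / "centroids.csv"
            pd.DataFrame(cent_rows).to_csv(cent_csv, index=False)
            emit(cent_csv)
            manifest["stages"].append({"stage": stage, "n_stations": len(ensembles),
                                       "config": dataclasses.asdict(bt_cfg)})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - halt with stage name, keep partials
        raise StageError(stage, str(exc)) from exc

    for p in outputs:
        manifest["outputs"][p.name] = _sha256(p)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
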