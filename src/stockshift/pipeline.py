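"""Pipeline orchestration: one declarative config, composable stages.

A run proceeds simulate -> units -> interpolate -> allocate (plus an
optional port-threshold sensitivity sweep).  Every stage reads its inputs
from, and writes its outputs to, the run directory, so the staged CLI
subcommands compose to exactly the monolithic :func:`run_pipeline`.  All
randomness flows from the single config seed; reruns of the same config
are byte-identical.

Because port selection is stock-specific, the fishing-ports design yields
one regulatory-unit set per stock (written as
``units_fishing_ports_<stock>.csv``); the state-waters design is shared
(``units_state_waters.csv``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import allocation, interpolation, regulatory, synthetic

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "stage_simulate",
    "stage_units",
    "stage_interpolate",
    "stage_allocate",
    "stage_sensitivity",
    "demo_config",
    "study_config",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run.

    Inputs come either from the synthetic generator (``geography`` params
    plus ``stocks`` scenarios) or from files (``geography_path``,
    ``surveys_path``, ``ports_path``, ``landings_path``).
    """

    out_dir: str
    buffer_radius: float  # port-buffer radius, degrees (no field default exists)
    seed: int = 0
    resolution: float = regulatory.DEFAULT_RESOLUTION
    origin: tuple | None = None
    geography: dict | None = None
    stocks: list = field(default_factory=list)
    geography_path: str | None = None
    surveys_path: str | None = None
    ports_path: str | None = None
    landings_path: str | None = None
    ports_per_state: int = 3
    landings_years: tuple | None = None
    port_threshold: float = 0.25
    reference_periods: dict = field(default_factory=dict)
    current_period: tuple = (2010, 2019)
    seasonal_method: str = "state_waters"
    running_mean_window: int = 10
    quota_path: str | None = None
    sensitivity_thresholds: list | None = None

    def __post_init__(self):
        if not 0.0 < self.port_threshold <= 1.0:
            raise ValueError("port_threshold must be in (0, 1]")
        if self.buffer_radius <= 0:
            raise ValueError("buffer_radius must be > 0")
        self.current_period = tuple(self.current_period)
        if self.landings_years is not None:
            self.landings_years = tuple(self.landings_years)
        if self.origin is not None:
            self.origin = tuple(self.origin)
        self.reference_periods = {k: tuple(v) for k, v in self.reference_periods.items()}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        grid = data.pop("grid", None)
        if grid:
            data.setdefault("resolution", grid.get("resolution", regulatory.DEFAULT_RESOLUTION))
            if grid.get("origin") is not None:
                data.setdefault("origin", grid["origin"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        # json round-trip normalizes nested tuples to lists (YAML-stable)
        return json.loads(json.dumps(dataclasses.asdict(self)))

    # -- derived objects ----------------------------------------------

    def scenario(self, idx: int) -> synthetic.StockScenario:
        spec = dict(self.stocks[idx])
        spec.setdefault("seed", self.seed * 1000 + idx)
        spec["center0"] = tuple(spec["center0"])
        spec["spread"] = tuple(spec["spread"])
        spec["years"] = tuple(spec["years"])
        return synthetic.StockScenario(**spec)

    @property
    def scenarios(self) -> list:
        return [self.scenario(i) for i in range(len(self.stocks))]

    @property
    def run_dir(self) -> Path:
        return Path(self.out_dir)


# ---------------------------------------------------------------------------
# shared loaders


def _load_geography(cfg: PipelineConfig) -> synthetic.Geography:
    if cfg.geography_path:
        return synthetic.read_geography(cfg.geography_path)
    path = cfg.run_dir / "geography.geojson"
    if path.exists():
        return synthetic.read_geography(path)
    if cfg.geography:
        return synthetic.make_geography(**cfg.geography)
    raise FileNotFoundError("no geography available: run the simulate stage or set paths")


def _load_csv(cfg: PipelineConfig, explicit: str | None, name: str) -> pd.DataFrame:
    path = Path(explicit) if explicit else cfg.run_dir / name
    if not path.exists():
        raise FileNotFoundError(f"missing input {path}")
    return pd.read_csv(path)


def _grid(cfg: PipelineConfig, geo: synthetic.Geography) -> regulatory.GridSpec:
    return regulatory.build_grid(geo.eez, cfg.resolution, cfg.origin)


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate geography, surveys, ports and landings into the run dir."""
    if not cfg.stocks or not cfg.geography:
        raise ValueError("simulate stage needs 'geography' and 'stocks' in the config")
    geo = synthetic.make_geography(**cfg.geography)
    scens = cfg.scenarios
    surveys = pd.concat([synthetic.simulate_surveys(geo, s) for s in scens], ignore_index=True)
    ports, landings = synthetic.simulate_ports_landings(
        geo,
        scens,
        ports_per_state=cfg.ports_per_state,
        landings_years=cfg.landings_years,
        seed=cfg.seed * 1000 + 999,
    )
    run = cfg.run_dir
    run.mkdir(parents=True, exist_ok=True)
    synthetic.write_geography(geo, run / "geography.geojson")
    return {
        "geography": run / "geography.geojson",
        "surveys": _write(surveys, run / "surveys.csv"),
        "ports": _write(ports, run / "ports.csv"),
        "landings": _write(landings, run / "landings.csv"),
    }


def stage_units(cfg: PipelineConfig) -> dict:
    """Build both regulatory-unit designs and write their weight tables."""
    geo = _load_geography(cfg)
    grid = _grid(cfg, geo)
    ports = _load_csv(cfg, cfg.ports_path, "ports.csv")
    landings = _load_csv(cfg, cfg.landings_path, "landings.csv")
    period = cfg.landings_years or cfg.current_period

    out = {}
    sw = regulatory.expand_state_waters(geo, grid)
    out["state_waters"] = _write(
        regulatory.units_to_frame(sw), cfg.run_dir / "units_state_waters.csv"
    )
    for stock in sorted(landings["stock"].unique()):
        selected = regulatory.select_top_ports(
            landings, ports, stock, period, threshold=cfg.port_threshold
        )
        fp = regulatory.expand_fishing_ports(
            selected, grid, geo.eez, cfg.buffer_radius, state_waters=geo
        )
        out[f"fishing_ports_{stock}"] = _write(
            regulatory.units_to_frame(fp), cfg.run_dir / f"units_fishing_ports_{stock}.csv"
        )
    return out


def stage_interpolate(cfg: PipelineConfig) -> dict:
    """Interpolate every stock x year x season survey group onto the grid."""
    geo = _load_geography(cfg)
    grid = _grid(cfg, geo)
    surveys = _load_csv(cfg, cfg.surveys_path, "surveys.csv")
    surfaces, skips = interpolation.batch_interpolate(surveys, grid)
    return {
        "surfaces": _write(interpolation.surfaces_to_frame(surfaces), cfg.run_dir / "surfaces.csv"),
        "skip_report": _write(skips, cfg.run_dir / "skip_report.csv"),
    }


def _load_units(cfg: PipelineConfig, stocks) -> dict:
    """method -> RegulatoryUnits (state_waters) or {stock: RegulatoryUnits}."""
    sw = regulatory.frame_to_units(pd.read_csv(cfg.run_dir / "units_state_waters.csv"))
    fp = {
        stock: regulatory.frame_to_units(
            pd.read_csv(cfg.run_dir / f"units_fishing_ports_{stock}.csv")
        )
        for stock in stocks
    }
    return {"state_waters": sw, "fishing_ports": fp}


def stage_allocate(cfg: PipelineConfig) -> dict:
    """Allocate surfaces to states; write proportions, change statistics,
    running means and the quota comparison."""
    geo = _load_geography(cfg)
    grid = _grid(cfg, geo)
    frame = pd.read_csv(cfg.run_dir / "surfaces.csv")
    surfaces = interpolation.frame_to_surfaces(frame, grid)
    stocks = sorted({s.stock for s in surfaces})
    missing = set(stocks) - set(cfg.reference_periods)
    if missing:
        raise ValueError(f"config lacks reference_periods for: {sorted(missing)}")
    units = _load_units(cfg, stocks)
    states = [sid for sid, _ in geo.state_waters]

    rows = []
    for surf in surfaces:
        for method, u in units.items():
            ru = u[surf.stock] if isinstance(u, dict) else u
            alphas = allocation.allocate_proportions(surf, ru)
            for sid in states:
                rows.append(
                    (surf.stock, surf.season, method, sid, surf.year, alphas.get(sid, 0.0))
                )
    series = pd.DataFrame(rows, columns=["stock", "season", "method", "state", "year", "alpha"])
    series = series.sort_values(
        ["stock", "season", "method", "state", "year"], ignore_index=True
    )

    deltas = allocation.delta_alpha_contrasts(
        series, cfg.reference_periods, cfg.current_period, cfg.seasonal_method
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rmeans = allocation.running_mean(series, cfg.running_mean_window)

    alpha_cur = _current_means(series, cfg)
    quota = (
        pd.read_csv(cfg.quota_path) if cfg.quota_path else _reference_quota(series, cfg)
    )
    qcomp = allocation.compare_to_quota(alpha_cur, quota)

    run = cfg.run_dir
    return {
        "proportions": _write(series, run / "proportions.csv"),
        "delta_alpha": _write(deltas, run / "delta_alpha.csv"),
        "running_mean": _write(rmeans, run / "running_mean.csv"),
        "quota_comparison": _write(qcomp, run / "quota_comparison.csv"),
    }


def _current_means(series: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for (stock, state, method, season), _ in series.groupby(
        ["stock", "state", "method", "season"], sort=True
    ):
        try:
            pm = allocation.period_mean(
                series, (stock, season, method, state), cfg.current_period
            )
            rows.append((stock, state, method, season, pm.value))
        except allocation.MissingPeriodError:
            continue
    return pd.DataFrame(rows, columns=["stock", "state", "method", "season", "alpha"])


def _reference_quota(series: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Baseline quota synthesized from the reference-period spring
    state-waters shares, normalized to 100 per stock — the 'historical
    landings' convention the current allocations encode."""
    rows = []
    for stock, ref in cfg.reference_periods.items():
        shares = {}
        for state in sorted(series["state"].unique()):
            try:
                pm = allocation.period_mean(series, (stock, "spring", "state_waters", state), ref)
                shares[state] = pm.value
            except allocation.MissingPeriodError:
                shares[state] = 0.0
        tot = sum(shares.values())
        for state, v in shares.items():
            rows.append((state, stock, 100.0 * v / tot if tot > 0 else 0.0))
    return pd.DataFrame(rows, columns=["state", "stock", "quota_pct"])


def stage_sensitivity(cfg: PipelineConfig) -> dict:
    """Port-threshold sensitivity sweep (per stock)."""
    if not cfg.sensitivity_thresholds:
        return {}
    geo = _load_geography(cfg)
    grid = _grid(cfg, geo)
    ports = _load_csv(cfg, cfg.ports_path, "ports.csv")
    landings = _load_csv(cfg, cfg.landings_path, "landings.csv")
    period = cfg.landings_years or cfg.current_period
    frames = []
    for stock in sorted(landings["stock"].unique()):
        tab = regulatory.threshold_sensitivity(
            landings,
            ports,
            grid,
            geo.eez,
            cfg.buffer_radius,
            cfg.sensitivity_thresholds,
            stock,
            period,
            state_waters=geo,
        )
        tab.insert(0, "stock", stock)
        frames.append(tab)
    return {"sensitivity": _write(pd.concat(frames, ignore_index=True), cfg.run_dir / "sensitivity.csv")}


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write a run manifest.

    Returns {output name: path}.  Any stage failure is re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    outputs: dict = {}
    stages = [
        ("simulate", stage_simulate),
        ("units", stage_units),
        ("interpolate", stage_interpolate),
        ("allocate", stage_allocate),
        ("sensitivity", stage_sensitivity),
    ]
    for name, fn in stages:
        if name == "simulate" and not cfg.stocks:
            continue  # inputs come from files
        try:
            outputs.update(fn(cfg))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(name, exc) from exc

    cfg_dict = cfg.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    skips = pd.read_csv(cfg.run_dir / "skip_report.csv")
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "n_skipped_groups": int(len(skips)),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    with open(cfg.run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = cfg.run_dir / "manifest.json"
    return outputs


# ---------------------------------------------------------------------------
# canned configurations


def study_config(out_dir, seed: int = 11) -> PipelineConfig:
    """The full synthetic study: 11 states, one scup-like stock drifting
    0.1 deg/yr poleward over 40 years with a 1.5 deg fall displacement."""
    scen = synthetic.default_scenario()
    return PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        buffer_radius=0.75,
        resolution=0.3,
        geography=dict(
            n_states=11,
            lat_range=(33.8, 45.2),
            eez_width=3.0,
            state_waters_width=0.2,
            coastline_meridian=-74.0,
        ),
        stocks=[
            dict(
                stock_id=scen.stock_id,
                center0=list(scen.center0),
                drift=scen.drift,
                seasonal_offset=scen.seasonal_offset,
                spread=list(scen.spread),
                peak_cpue=scen.peak_cpue,
                noise_sd=scen.noise_sd,
                years=list(scen.years),
                stations_per_year=scen.stations_per_year,
            )
        ],
        ports_per_state=3,
        landings_years=(2010, 2019),
        reference_periods={scen.stock_id: (1980, 1986)},
        current_period=(2010, 2019),
        sensitivity_thresholds=[0.1, 0.25, 0.5, 0.75, 1.0],
    )


def demo_config(out_dir, seed: int = 3) -> PipelineConfig:
    """A 1-minute smoke configuration: 2 states, 2 stocks, 20 years."""
    return PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        buffer_radius=0.8,
        resolution=0.5,
        geography=dict(
            n_states=2,
            lat_range=(38.0, 44.0),
            eez_width=2.0,
            state_waters_width=0.3,
            coastline_meridian=-74.0,
        ),
        stocks=[
            dict(
                stock_id="drifter",
                center0=[-73.0, 39.5],
                drift=0.15,
                seasonal_offset=1.0,
                spread=[0.8, 1.2],
                peak_cpue=40.0,
                noise_sd=0.5,
                years=[2000, 2019],
                stations_per_year=60,
            ),
            dict(
                stock_id="homebody",
                center0=[-73.0, 41.0],
                drift=0.0,
                seasonal_offset=0.5,
                spread=[0.8, 1.0],
                peak_cpue=25.0,
                noise_sd=0.5,
                years=[2000, 2019],
                stations_per_year=60,
            ),
        ],
        ports_per_state=2,
        landings_years=(2010, 2019),
        reference_periods={"drifter": (2000, 2005), "homebody": (2000, 2005)},
        current_period=(2010, 2019),
    )
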