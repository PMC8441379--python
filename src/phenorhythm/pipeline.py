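"""End-to-end runs: simulate -> preprocess -> traits -> rhythm statistics.

A run is driven by a :class:`RunConfig` (YAML-loadable).  Every output CSV
carries a header comment with the config hash and seed; a ``manifest.json``
records the config echo, package/library versions and per-file checksums so
deterministic stages can be verified bit-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cloud import PointCloud
from .io import write_cloud
from .leaf_traits import leaf_traits_all
from .plant_traits import plant_traits_all
from .preprocess import cluster_plants, normalize_height, remove_outliers
from .rhythm import circadian_pipeline, tukey_cld
from .synth import (
    CircadianModel,
    EnvModel,
    GrowthModel,
    default_circadian_model,
    default_growth_model,
    random_plant_spec,
    sample_plant,
    grow_spec,
    modulate_spec,
    simulate_env,
)

logger = logging.getLogger("phenorhythm")

#: Table-1 style observation schedules (clock times; day offsets relative to
#: the first scan's date)
CIRCADIAN_SCHEDULE: List[Tuple[int, str]] = [
    (0, "19:49"), (0, "21:48"), (0, "23:48"),
    (1, "01:48"), (1, "03:48"), (1, "04:48"), (1, "06:48"), (1, "08:48"),
    (1, "10:48"), (1, "12:00"), (1, "12:48"), (1, "14:48"), (1, "16:48"),
    (1, "18:48"), (1, "19:48"), (1, "21:48"),
]

STAGE_DAYS = (67, 78, 98, 112)


@dataclass
class RunConfig:
    """All tunables for a reproducible pipeline run."""

    outdir: str = "run_output"
    mode: str = "seasonal"  # seasonal | circadian_standard | circadian_stress
    seed: int = 0
    n_plants: int = 10
    density: float = 5.0e4  # points / m^2
    noise_sd: float = 0.002  # m
    cell_size: float = 0.005  # m, projected-area grid
    voxel: float = 0.02  # m, 3DPI voxel
    n_slices: int = 30
    alpha: float = 0.05
    sor_k: int = 20
    sor_nsigma: float = 3.0
    dtm_cell: float = 0.25
    cluster_radius: float = 0.3
    grid_spacing: float = 0.6
    stage_days: Tuple[int, ...] = STAGE_DAYS
    rate_anchor_days: Tuple[int, int] = (78, 112)
    detrend_t0: Optional[float] = None
    preprocess: bool = False
    write_clouds: bool = False

    def validate(self) -> None:
        if self.mode not in ("seasonal", "circadian_standard", "circadian_stress"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.density <= 0 or self.noise_sd < 0:
            raise ValueError("density must be > 0 and noise_sd >= 0")
        if min(self.cell_size, self.voxel, self.dtm_cell, self.cluster_radius) <= 0:
            raise ValueError("grid sizes must be > 0")
        if len(self.stage_days) < 2 or list(self.stage_days) != sorted(self.stage_days):
            raise ValueError("stage_days must be increasing")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stage_days", "rate_anchor_days"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phenorhythm {__version__} config={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def _plant_centers(config: RunConfig) -> List[Tuple[float, float]]:
    side = int(np.ceil(np.sqrt(config.n_plants)))
    centers = []
    for i in range(config.n_plants):
        centers.append((config.grid_spacing * (i % side), config.grid_spacing * (i // side)))
    return centers


def _preprocess_cloud(cloud: PointCloud, config: RunConfig) -> PointCloud:
    cloud = remove_outliers(cloud, k_neighbors=config.sor_k, n_sigma=config.sor_nsigma)
    cloud = normalize_height(cloud, cell_size=config.dtm_cell)
    return cloud


def _extract_tables(
    clouds_per_moment: Dict[object, List[Tuple[int, Tuple[float, float], PointCloud]]],
    config: RunConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    plant_rows, leaf_rows = [], []
    for moment, plants in clouds_per_moment.items():
        for plant_id, base_xy, cloud in plants:
            traits = plant_traits_all(cloud, cell_size=config.cell_size, voxel=config.voxel)
            row = {"moment": moment, "plant": plant_id, **traits.as_dict()}
            plant_rows.append(row)
            for lab in cloud.leaf_labels():
                leaf = cloud.leaf(lab)
                # young leaves carry few points; keep >= ~10 points per slice
                n_slices = int(max(5, min(config.n_slices, len(leaf) // 10)))
                lt = leaf_traits_all(
                    leaf,
                    n_slices=n_slices,
                    cell_size=config.cell_size,
                    stem_xy=base_xy,
                    sensor_sd=config.noise_sd,
                )
                leaf_rows.append(
                    {"moment": moment, "plant": plant_id, "leaf": int(lab), **lt.as_dict()}
                )
    return pd.DataFrame(plant_rows), pd.DataFrame(leaf_rows)


def _seasonal_letters(trait_table: pd.DataFrame, config: RunConfig, level: str) -> pd.DataFrame:
    rows = []
    moments = sorted(trait_table["moment"].unique())
    skip = {"moment", "plant", "leaf"}
    for trait in [c for c in trait_table.columns if c not in skip]:
        groups = [
            trait_table.loc[trait_table["moment"] == m, trait].dropna().to_numpy()
            for m in moments
        ]
        if any(len(g) < 2 for g in groups):
            continue
        res = tukey_cld(groups, alpha=config.alpha)
        for m, mean, sd, n, letter in zip(moments, res.means, res.sds, res.ns, res.letters):
            rows.append(
                {
                    "level": level,
                    "trait": trait,
                    "moment": m,
                    "mean": mean,
                    "sd": sd,
                    "n": n,
                    "letters": letter,
                }
            )
    return pd.DataFrame(rows)


def simulate_stand(
    config: RunConfig, moments: Sequence[datetime], planting_time: datetime
) -> Dict[object, List[Tuple[int, Tuple[float, float], PointCloud]]]:
    """Sample every plant at every moment (one RNG stream, deterministic)."""
    rng = np.random.default_rng(config.seed)
    growth = default_growth_model() if config.mode == "seasonal" else GrowthModel()
    circ = default_circadian_model() if config.mode.startswith("circadian") else CircadianModel()
    centers = _plant_centers(config)
    bases = [random_plant_spec(rng, base_xy=c) for c in centers]

    out: Dict[object, List[Tuple[int, Tuple[float, float], PointCloud]]] = {}
    for moment in moments:
        t_days = (moment - planting_time).total_seconds() / 86400.0
        clock_h = moment.hour + moment.minute / 60.0 + moment.second / 3600.0
        plants = []
        for pid, base in enumerate(bases):
            spec = modulate_spec(grow_spec(base, growth, t_days), circ, clock_h)
            cloud = sample_plant(spec, config.density, config.noise_sd, rng, plant_id=pid)
            plants.append((pid, base.base_xy, cloud))
        out[moment] = plants
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and return the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    planting = datetime(2019, 3, 25)
    if config.mode == "seasonal":
        moments = [planting + pd.Timedelta(days=int(d)) for d in config.stage_days]
    else:
        first_day = planting + pd.Timedelta(days=89)  # late bell-mouthed stage
        moments = [
            first_day
            + pd.Timedelta(days=d_off)
            + pd.Timedelta(hours=int(hhmm[:2]), minutes=int(hhmm[3:]))
            for d_off, hhmm in CIRCADIAN_SCHEDULE
        ]

    logger.info("stage=simulate mode=%s moments=%d", config.mode, len(moments))
    stand = simulate_stand(config, moments, planting)

    if config.preprocess:
        logger.info("stage=preprocess sor_k=%d", config.sor_k)
        stand = {
            m: [(pid, xy, _preprocess_cloud(c, config)) for pid, xy, c in plants]
            for m, plants in stand.items()
        }

    if config.write_clouds:
        cloud_dir = outdir / "clouds"
        cloud_dir.mkdir(exist_ok=True)
        for m, plants in stand.items():
            stamp = pd.Timestamp(m).strftime("%Y%m%dT%H%M")
            for pid, _xy, cloud in plants:
                write_cloud(cloud, cloud_dir / f"{stamp}_plant{pid}.xyz")

    logger.info("stage=traits plants=%d", config.n_plants)
    plant_table, leaf_table = _extract_tables(stand, config)
    _write_csv(plant_table, outdir / "plant_traits.csv", config)
    _write_csv(leaf_table, outdir / "leaf_traits.csv", config)

    outputs = ["plant_traits.csv", "leaf_traits.csv"]
    if config.mode == "seasonal":
        logger.info("stage=seasonal alpha=%g", config.alpha)
        letters = pd.concat(
            [
                _seasonal_letters(plant_table, config, "plant"),
                _seasonal_letters(leaf_table.drop(columns=["leaf"]), config, "leaf"),
            ],
            ignore_index=True,
        )
        _write_csv(letters, outdir / "seasonal_letters.csv", config)
        outputs.append("seasonal_letters.csv")
    else:
        logger.info("stage=circadian")
        env_model = EnvModel()
        env = simulate_env(
            env_model,
            pd.Timestamp(min(moments)).floor("30min").to_pydatetime(),
            pd.Timestamp(max(moments)).ceil("30min").to_pydatetime(),
            step_min=30.0,
            seed=config.seed + 1,
        )
        _write_csv(env, outdir / "env.csv", config)
        series, corr = circadian_pipeline(
            plant_table.drop(columns=["plant"]), env, seasonal_anchors=None, t0=config.detrend_t0
        )
        _write_csv(series, outdir / "circadian_series_plant.csv", config)
        _write_csv(corr, outdir / "env_correlation_plant.csv", config)
        series_l, corr_l = circadian_pipeline(
            leaf_table.drop(columns=["plant", "leaf"]), env, seasonal_anchors=None,
            t0=config.detrend_t0,
        )
        _write_csv(series_l, outdir / "circadian_series_leaf.csv", config)
        _write_csv(corr_l, outdir / "env_correlation_leaf.csv", config)
        outputs += [
            "env.csv",
            "circadian_series_plant.csv",
            "env_correlation_plant.csv",
            "circadian_series_leaf.csv",
            "env_correlation_leaf.csv",
        ]

    checksums = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest() for name in outputs
    }
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "outputs": checksums,
        "elapsed_s": round(time.time() - t_start, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("stage=done elapsed=%.1fs", time.time() - t_start)
    return outdir
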