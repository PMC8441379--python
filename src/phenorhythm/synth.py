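"""Synthetic maize stand generator with closed-form ground truth.

Plants are built from a vertical stem cylinder plus ruled-surface leaves
whose midrib is a straight base-to-tip chord with a parabolic downward sag
("droop") and a sine-arch width profile.  Every generating parameter (leaf
length, width, inclination, azimuth, heights) is recorded so downstream
trait extraction can be validated by parameter recovery.

Growth across a season follows logistic curves; day-scale movement is a
24 h sinusoid added on top.  Environmental series (PAR / temperature /
relative humidity) follow simple diurnal curves sampled at a fixed cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cloud import PointCloud

__all__ = [
    "LeafSpec",
    "PlantSpec",
    "LogisticCurve",
    "GrowthModel",
    "CircadianModel",
    "EnvModel",
    "random_leaf_spec",
    "random_plant_spec",
    "default_growth_model",
    "default_circadian_model",
    "sample_leaf",
    "sample_plant",
    "grow_spec",
    "modulate_spec",
    "simulate_series",
    "simulate_env",
]

_GAUSS_N = 96  # fixed-order Gauss-Legendre nodes for arc-length quadrature


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafSpec:
    """Parametric leaf: midrib chord + parabolic droop + sine-arch width.

    ``length`` is the true midrib arc length (m); ``inclination_deg`` is the
    elevation of the base->tip chord above horizontal in [0, 90];
    ``azimuth_deg`` is the clockwise angle from north of the base->tip
    direction in [0, 360); ``droop`` in [0, 0.5] scales the parabolic sag of
    the midrib (max sag = droop * chord length at mid-leaf).
    ``width_profile`` is the exponent p of width(s) = max_width * sin(pi s)^p.
    """

    length: float
    max_width: float
    attach_height: float
    inclination_deg: float
    azimuth_deg: float
    droop: float = 0.0
    width_profile: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("leaf length must be > 0")
        if self.max_width <= 0:
            raise ValueError("leaf max_width must be > 0")
        if not 0.0 <= self.inclination_deg <= 90.0:
            raise ValueError("inclination_deg must be in [0, 90]")
        if not 0.0 <= self.droop <= 0.5:
            raise ValueError("droop must be in [0, 0.5]")
        object.__setattr__(self, "azimuth_deg", float(self.azimuth_deg) % 360.0)

    # -- closed-form geometry ----------------------------------------------

    def _chord_unit(self) -> np.ndarray:
        az = np.deg2rad(self.azimuth_deg)
        inc = np.deg2rad(self.inclination_deg)
        return np.array(
            [np.cos(inc) * np.sin(az), np.cos(inc) * np.cos(az), np.sin(inc)]
        )

    def _lateral_unit(self) -> np.ndarray:
        az = np.deg2rad(self.azimuth_deg)
        return np.array([np.cos(az), -np.sin(az), 0.0])

    def _speed_factor(self, s: np.ndarray) -> np.ndarray:
        """|dm/ds| / chord_length at parameter s."""
        uz = np.sin(np.deg2rad(self.inclination_deg))
        d = self.droop
        return np.sqrt(1.0 - 8.0 * d * uz * (1.0 - 2.0 * s) + 16.0 * d * d * (1.0 - 2.0 * s) ** 2)

    @property
    def chord_length(self) -> float:
        """Straight base->tip chord length consistent with the arc length."""
        nodes, weights = np.polynomial.legendre.leggauss(_GAUSS_N)
        s = 0.5 * (nodes + 1.0)
        integral = 0.5 * np.sum(weights * self._speed_factor(s))
        return self.length / integral

    def midrib_points(self, s: np.ndarray, base_xy=(0.0, 0.0)) -> np.ndarray:
        """Midrib coordinates at parameters s in [0, 1] (s=0 at the base)."""
        s = np.asarray(s, dtype=float)
        lc = self.chord_length
        base = np.array([base_xy[0], base_xy[1], self.attach_height])
        pts = base[None, :] + np.outer(s * lc, self._chord_unit())
        pts[:, 2] -= 4.0 * self.droop * lc * s * (1.0 - s)
        return pts

    def width_at(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.max_width * np.sin(np.pi * s) ** self.width_profile

    @property
    def surface_area(self) -> float:
        """True ruled-surface area = integral of width(s) ds_arc."""
        nodes, weights = np.polynomial.legendre.leggauss(_GAUSS_N)
        s = 0.5 * (nodes + 1.0)
        lc = self.chord_length
        return 0.5 * np.sum(weights * self.width_at(s) * lc * self._speed_factor(s))

    @property
    def tip_height(self) -> float:
        return self.attach_height + self.chord_length * np.sin(np.deg2rad(self.inclination_deg))

    @property
    def apex_height(self) -> float:
        """Max z over the midrib (sag can push the apex below the tip)."""
        s = np.linspace(0.0, 1.0, 513)
        return float(self.midrib_points(s)[:, 2].max())


@dataclass(frozen=True)
class PlantSpec:
    """Stem cylinder plus an ordered list of leaves."""

    stem_height: float
    stem_radius: float = 0.01
    base_xy: Tuple[float, float] = (0.0, 0.0)
    leaves: Tuple[LeafSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.stem_height <= 0:
            raise ValueError("stem_height must be > 0")
        if self.stem_radius <= 0:
            raise ValueError("stem_radius must be > 0")
        object.__setattr__(self, "leaves", tuple(self.leaves))
        for leaf in self.leaves:
            if leaf.attach_height > self.stem_height + 1e-9:
                raise ValueError("leaf attach_height exceeds stem_height")

    @property
    def apex_height(self) -> float:
        """Highest point of the plant (stem top or highest leaf midrib)."""
        h = self.stem_height
        for leaf in self.leaves:
            h = max(h, leaf.apex_height)
        return h


# --------------------------------------------------------------------------
# growth / circadian / environment models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticCurve:
    """trait(t) = L / (1 + exp(-r (t - t_mid))), t in days after planting."""

    plateau: float
    rate: float
    t_mid: float

    def __call__(self, t_days: float) -> float:
        return self.plateau / (1.0 + np.exp(-self.rate * (t_days - self.t_mid)))

    def fraction(self, t_days: float) -> float:
        """Value as a fraction of the plateau, in (0, 1)."""
        return 1.0 / (1.0 + np.exp(-self.rate * (t_days - self.t_mid)))


#: fields of PlantSpec/LeafSpec a GrowthModel may govern
GROWTH_FIELDS = ("stem_height", "leaf_length", "leaf_width")


@dataclass(frozen=True)
class GrowthModel:
    """Per-trait logistic curves; the base spec is taken as the plateau."""

    curves: Dict[str, LogisticCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.curves:
            if name not in GROWTH_FIELDS:
                raise ValueError(f"unknown growth field {name!r}; expected one of {GROWTH_FIELDS}")


#: spec fields a CircadianModel may modulate (additively, in field units)
CIRCADIAN_FIELDS = (
    "stem_height",
    "attach_height",
    "inclination_deg",
    "azimuth_deg",
    "leaf_length",
    "leaf_width",
)


@dataclass(frozen=True)
class CircadianModel:
    """Additive 24 h sinusoid per field: base + amp * sin(2 pi (h - phase)/24).

    ``terms`` maps a field name to (amplitude, phase_h); amplitude is in the
    field's own units (m or degrees) and must be >= 0.
    """

    terms: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (amp, _phase) in self.terms.items():
            if name not in CIRCADIAN_FIELDS:
                raise ValueError(f"unknown circadian field {name!r}")
            if amp < 0:
                raise ValueError("circadian amplitude must be >= 0")

    def offset(self, name: str, clock_h: float) -> float:
        if name not in self.terms:
            return 0.0
        amp, phase = self.terms[name]
        return amp * np.sin(2.0 * np.pi * (clock_h - phase) / 24.0)


@dataclass(frozen=True)
class EnvModel:
    """Diurnal PAR / temperature / relative-humidity curves.

    PAR is a half-sine between sunrise and sunset (0 at night); T is a 24 h
    sinusoid peaking at ``t_peak_hour``; RH is in anti-phase to T.
    """

    par_peak: float = 1800.0
    t_min: float = 18.0
    t_max: float = 32.0
    t_peak_hour: float = 14.0
    rh_min: float = 40.0
    rh_max: float = 85.0
    sunrise_h: float = 4.77  # 04:46
    sunset_h: float = 19.77  # 19:46

    def __post_init__(self) -> None:
        if self.par_peak < 0:
            raise ValueError("par_peak must be >= 0")
        if not (0 <= self.rh_min <= self.rh_max <= 100):
            raise ValueError("RH bounds must satisfy 0 <= min <= max <= 100")
        if self.sunrise_h >= self.sunset_h:
            raise ValueError("sunrise must precede sunset")

    def par(self, clock_h: np.ndarray) -> np.ndarray:
        clock_h = np.asarray(clock_h, dtype=float)
        day = (clock_h >= self.sunrise_h) & (clock_h <= self.sunset_h)
        phase = np.pi * (clock_h - self.sunrise_h) / (self.sunset_h - self.sunrise_h)
        return np.where(day, self.par_peak * np.clip(np.sin(phase), 0.0, None), 0.0)

    def temperature(self, clock_h: np.ndarray) -> np.ndarray:
        clock_h = np.asarray(clock_h, dtype=float)
        mid = 0.5 * (self.t_min + self.t_max)
        amp = 0.5 * (self.t_max - self.t_min)
        return mid + amp * np.cos(2.0 * np.pi * (clock_h - self.t_peak_hour) / 24.0)

    def humidity(self, clock_h: np.ndarray) -> np.ndarray:
        clock_h = np.asarray(clock_h, dtype=float)
        mid = 0.5 * (self.rh_min + self.rh_max)
        amp = 0.5 * (self.rh_max - self.rh_min)
        return mid - amp * np.cos(2.0 * np.pi * (clock_h - self.t_peak_hour) / 24.0)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def random_leaf_spec(
    rng: np.random.Generator,
    attach_height: float,
    azimuth_deg: Optional[float] = None,
) -> LeafSpec:
    """A leaf with dimensions in the generator's default testable ranges."""
    return LeafSpec(
        length=rng.uniform(0.35, 0.6),
        max_width=rng.uniform(0.07, 0.12),
        attach_height=attach_height,
        inclination_deg=rng.uniform(5.0, 60.0),
        azimuth_deg=rng.uniform(0.0, 360.0) if azimuth_deg is None else azimuth_deg,
        droop=rng.uniform(0.0, 0.3),
    )


def random_plant_spec(
    rng: np.random.Generator,
    n_leaves: Optional[int] = None,
    stem_height: Optional[float] = None,
    base_xy: Tuple[float, float] = (0.0, 0.0),
) -> PlantSpec:
    """A plateau-sized maize plant with 5-15 leaves on alternating sides."""
    if n_leaves is None:
        n_leaves = int(rng.integers(5, 16))
    if stem_height is None:
        stem_height = float(rng.uniform(1.95, 2.05))
    side = rng.uniform(0.0, 360.0)
    leaves = []
    for i in range(n_leaves):
        attach = stem_height * (0.15 + 0.75 * (i + 1) / (n_leaves + 1))
        az = (side + 180.0 * i + rng.normal(0.0, 15.0)) % 360.0
        leaves.append(random_leaf_spec(rng, attach_height=attach, azimuth_deg=az))
    return PlantSpec(stem_height=stem_height, base_xy=base_xy, leaves=tuple(leaves))


def default_growth_model(rate: float = 0.25, t_mid: float = 70.0) -> GrowthModel:
    """Logistic season that plateaus between the heading and maturity stages.

    Leaves expand a little more slowly than the stem so leaf-area traits
    keep growing visibly into the third stage before levelling off.
    """
    return GrowthModel(
        curves={
            "stem_height": LogisticCurve(1.0, rate, t_mid),
            "leaf_length": LogisticCurve(1.0, 0.72 * rate, t_mid),
            "leaf_width": LogisticCurve(1.0, 0.72 * rate, t_mid),
        }
    )


def default_circadian_model() -> CircadianModel:
    """Mild day-scale movement in heights and leaf angles."""
    return CircadianModel(
        terms={
            "stem_height": (0.01, 6.0),
            "inclination_deg": (3.0, 8.0),
            "azimuth_deg": (2.0, 10.0),
        }
    )


def sample_leaf(
    spec: LeafSpec,
    density: float,
    noise_sd: float,
    seed,
    *,
    base_xy: Tuple[float, float] = (0.0, 0.0),
    label: int = 1,
) -> PointCloud:
    """Sample points on the leaf surface at ``density`` points/m^2.

    The point count is Poisson(density * surface_area); positions are drawn
    uniformly with respect to surface area, then isotropic Gaussian noise of
    sd ``noise_sd`` is added.  All labels equal ``label``.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = rng.poisson(density * spec.surface_area)
    if n == 0:
        return PointCloud(np.empty((0, 3)), np.empty(0, dtype=np.int64))

    # inverse-CDF sampling of s with pdf proportional to width(s)*|m'(s)|
    grid = np.linspace(0.0, 1.0, 2049)
    pdf = spec.width_at(grid) * spec._speed_factor(grid)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    s = np.interp(rng.random(n), cdf, grid)
    v = rng.random(n) - 0.5

    pts = spec.midrib_points(s, base_xy=base_xy)
    pts += np.outer(v * spec.width_at(s), spec._lateral_unit())
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return PointCloud(pts, np.full(n, label, dtype=np.int64))


def _sample_stem(spec: PlantSpec, density: float, noise_sd: float, rng: np.random.Generator) -> PointCloud:
    area = 2.0 * np.pi * spec.stem_radius * spec.stem_height
    n = rng.poisson(density * area)
    theta = rng.random(n) * 2.0 * np.pi
    z = rng.random(n) * spec.stem_height
    bx, by = spec.base_xy
    pts = np.column_stack(
        [bx + spec.stem_radius * np.cos(theta), by + spec.stem_radius * np.sin(theta), z]
    )
    # deterministic apex point so max z equals stem_height exactly at zero noise
    pts = np.vstack([pts, [bx, by, spec.stem_height]])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return PointCloud(pts, np.zeros(len(pts), dtype=np.int64))


def sample_plant(
    spec: PlantSpec,
    density: float,
    noise_sd: float,
    seed,
    *,
    plant_id: int = 0,
) -> PointCloud:
    """Sample the whole plant: stem (label 0) plus leaves (labels 1..K)."""
    if density <= 0:
        raise ValueError("density must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cloud = _sample_stem(spec, density, noise_sd, rng)
    for k, leaf in enumerate(spec.leaves, start=1):
        cloud = cloud.concat(
            sample_leaf(leaf, density, noise_sd, rng, base_xy=spec.base_xy, label=k)
        )
    cloud.plant_ids = np.full(len(cloud), plant_id, dtype=np.int64)
    return cloud


# --------------------------------------------------------------------------
# growth and circadian modulation
# --------------------------------------------------------------------------

def grow_spec(base: PlantSpec, growth: GrowthModel, t_days: float) -> PlantSpec:
    """Scale the base (plateau) spec down to its size at ``t_days``.

    Each governed field is multiplied by the logistic fraction at ``t_days``;
    leaf attachment heights co-scale with the stem so the spec stays valid.
    """
    if t_days < 0:
        raise ValueError("t_days must be >= 0")
    f_stem = growth.curves["stem_height"].fraction(t_days) if "stem_height" in growth.curves else 1.0
    f_len = growth.curves["leaf_length"].fraction(t_days) if "leaf_length" in growth.curves else 1.0
    f_wid = growth.curves["leaf_width"].fraction(t_days) if "leaf_width" in growth.curves else 1.0

    leaves = tuple(
        replace(
            leaf,
            length=leaf.length * f_len,
            max_width=leaf.max_width * f_wid,
            attach_height=leaf.attach_height * f_stem,
        )
        for leaf in base.leaves
    )
    return replace(base, stem_height=base.stem_height * f_stem, leaves=leaves)


def modulate_spec(spec: PlantSpec, circ: CircadianModel, clock_h: float) -> PlantSpec:
    """Apply the additive 24 h sinusoid of ``circ`` at clock hour ``clock_h``."""
    if not 0.0 <= clock_h < 24.0:
        raise ValueError("clock_h must be in [0, 24)")

    d_stem = circ.offset("stem_height", clock_h)
    leaves = tuple(
        replace(
            leaf,
            length=leaf.length + circ.offset("leaf_length", clock_h),
            max_width=leaf.max_width + circ.offset("leaf_width", clock_h),
            attach_height=leaf.attach_height + circ.offset("attach_height", clock_h),
            inclination_deg=leaf.inclination_deg + circ.offset("inclination_deg", clock_h),
            azimuth_deg=(leaf.azimuth_deg + circ.offset("azimuth_deg", clock_h)) % 360.0,
        )
        for leaf in spec.leaves
    )
    return replace(spec, stem_height=spec.stem_height + d_stem, leaves=leaves)


# --------------------------------------------------------------------------
# series simulation
# --------------------------------------------------------------------------

def _truth_rows(moment, plant_id: int, spec: PlantSpec) -> List[dict]:
    rows = []
    for k, leaf in enumerate(spec.leaves, start=1):
        rows.append(
            {
                "moment": moment,
                "plant": plant_id,
                "leaf": k,
                "stem_height": spec.stem_height,
                "apex_height": spec.apex_height,
                "length": leaf.length,
                "max_width": leaf.max_width,
                "attach_height": leaf.attach_height,
                "inclination_deg": leaf.inclination_deg,
                "azimuth_deg": leaf.azimuth_deg,
                "droop": leaf.droop,
                "leaf_apex_height": leaf.apex_height,
                "surface_area": leaf.surface_area,
            }
        )
    if not spec.leaves:
        rows.append(
            {
                "moment": moment,
                "plant": plant_id,
                "leaf": 0,
                "stem_height": spec.stem_height,
                "apex_height": spec.apex_height,
            }
        )
    return rows


def simulate_series(
    base: PlantSpec,
    growth: Optional[GrowthModel],
    circ: Optional[CircadianModel],
    moments: Sequence[datetime],
    density: float,
    noise_sd: float,
    seed,
    *,
    planting_time: datetime,
) -> Tuple[List[PointCloud], pd.DataFrame]:
    """One cloud per observation moment, plus a truth table of spec values.

    Each cloud is ``sample_plant(modulate_spec(grow_spec(base, t), clock))``
    where t is days after ``planting_time`` and clock is the local hour.
    """
    moments = list(moments)
    if any(b <= a for a, b in zip(moments, moments[1:])):
        raise ValueError("moments must be strictly increasing")
    growth = growth or GrowthModel()
    circ = circ or CircadianModel()
    rng = np.random.default_rng(seed)

    clouds: List[PointCloud] = []
    rows: List[dict] = []
    for moment in moments:
        dt = moment - planting_time
        t_days = dt.total_seconds() / 86400.0
        clock_h = (moment.hour + moment.minute / 60.0 + moment.second / 3600.0) % 24.0
        spec_t = modulate_spec(grow_spec(base, growth, t_days), circ, clock_h)
        clouds.append(sample_plant(spec_t, density, noise_sd, rng))
        rows.extend(_truth_rows(moment, 0, spec_t))
    return clouds, pd.DataFrame(rows)


def simulate_env(
    env: EnvModel,
    start: datetime,
    end: datetime,
    step_min: float = 30.0,
    seed=None,
    *,
    noise_sd: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Fixed-cadence environmental records from ``start`` to ``end`` inclusive.

    Returns a DataFrame with columns ``time`` (timestamps), ``PAR``, ``T``,
    ``RH``.  ``noise_sd`` adds optional Gaussian measurement noise per
    channel; PAR stays >= 0 (and exactly 0 at night), RH stays in [0, 100].
    """
    if start >= end:
        raise ValueError("start must precede end")
    if step_min <= 0:
        raise ValueError("step_min must be > 0")
    rng = np.random.default_rng(seed)

    n_steps = int(np.floor((end - start).total_seconds() / (step_min * 60.0) + 1e-9))
    times = [start + timedelta(minutes=step_min * i) for i in range(n_steps + 1)]
    clock = np.array([t.hour + t.minute / 60.0 + t.second / 3600.0 for t in times])

    par = env.par(clock)
    temp = env.temperature(clock)
    rh = env.humidity(clock)
    if noise_sd[0] > 0:
        night = par == 0.0
        par = np.clip(par + rng.normal(0, noise_sd[0], par.shape), 0.0, None)
        par[night] = 0.0
    if noise_sd[1] > 0:
        temp = temp + rng.normal(0, noise_sd[1], temp.shape)
    if noise_sd[2] > 0:
        rh = np.clip(rh + rng.normal(0, noise_sd[2], rh.shape), 0.0, 100.0)

    return pd.DataFrame({"time": pd.to_datetime(times), "PAR": par, "T": temp, "RH": rh})
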