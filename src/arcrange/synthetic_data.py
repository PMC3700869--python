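"""Synthetic categorical landscapes and cover-biased GPS tracks.

No telemetry or imagery ships with the package, so every downstream stage is
exercised on data with known ground truth:

* Landscapes are smoothed Gaussian random fields thresholded at the target
  class quantiles, so realized class proportions track the targets while a
  single ``aggregation`` parameter (the smoothing length in cells) controls
  patch clumping. The default emulates a low-heterogeneity Arctic mosaic of
  10 vegetation covers plus ~35% water on a 28.5-m grid.
* Movement is a biased correlated random walk: gamma step lengths, von Mises
  turning angles, and Metropolis-style thinning of proposed destinations with
  acceptance probability proportional to exp(seasonal log-weight of the
  destination cover), capped at 10 proposals per step. Seasonal preferences
  switch at programmed week breaks; water is strongly avoided by default.
  Fixes are emitted every 4 h from 1 April, mirroring a GPS collar schedule.

The generator records its programmed truth (per-season log-weights, statuses,
season breaks) so tests can measure parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo_io import CoverRaster

COVER_CLASSES = [
    "open spruce forest",
    "closed spruce forest",
    "deciduous forest",
    "dwarf shrub",
    "low shrub upland",
    "low shrub lowland",
    "tall shrub",
    "sparse vegetation",
    "tussock/lichen",
    "wet herbaceous",
    "water",
]

DEFAULT_PROPORTIONS = {
    "open spruce forest": 0.06,
    "closed spruce forest": 0.05,
    "deciduous forest": 0.03,
    "dwarf shrub": 0.09,
    "low shrub upland": 0.10,
    "low shrub lowland": 0.08,
    "tall shrub": 0.05,
    "sparse vegetation": 0.04,
    "tussock/lichen": 0.10,
    "wet herbaceous": 0.05,
    "water": 0.35,
}

# seasonal log-selection weights (unlisted covers weight 0; water avoided)
DEFAULT_SEASONAL_PREFERENCE = {
    1: {
        "sparse vegetation": 1.5,
        "tall shrub": 1.0,
        "closed spruce forest": 1.0,
        "low shrub upland": 0.8,
        "wet herbaceous": 0.7,
        "water": -2.5,
    },
    2: {"sparse vegetation": 1.5, "low shrub lowland": 1.5, "water": -2.5},
    3: {
        "low shrub lowland": 1.5,
        "sparse vegetation": 1.2,
        "closed spruce forest": 1.0,
        "tall shrub": 1.0,
        "water": -2.5,
    },
}

STATUSES = ["solitary", "cub-of-year", "cub1plus"]


@dataclass
class LandscapeSpec:
    """Recipe for a categorical landscape raster."""

    n_rows: int = 512
    n_cols: int = 512
    cell_size: float = 28.5
    cover_classes: list = field(default_factory=lambda: list(COVER_CLASSES))
    target_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    aggregation: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.cover_classes) < 1:
            raise ValueError("need at least one cover class")
        if self.aggregation < 0:
            raise ValueError("aggregation must be >= 0")
        total = sum(self.target_proportions[c] for c in self.cover_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target proportions sum to {total}, not 1")
        water = [c for c in self.cover_classes if c == "water"]
        if len(self.cover_classes) > 1 and len(water) != 1:
            raise ValueError("cover_classes must include exactly one water class")


@dataclass
class MovementSpec:
    """Recipe for cover-biased correlated-random-walk GPS tracks."""

    n_animals: int = 30
    fixes_per_animal: tuple[int, int] = (279, 959)
    fix_interval_hours: float = 4.0
    step_scale: float = 300.0
    turn_concentration: float = 1.0
    seasonal_preference: dict = field(
        default_factory=lambda: {
            s: dict(w) for s, w in DEFAULT_SEASONAL_PREFERENCE.items()
        }
    )
    season_breaks: list = field(default_factory=lambda: [31, 39])
    status_probs: dict = field(
        default_factory=lambda: {
            "solitary": 19 / 43,
            "cub-of-year": 6 / 43,
            "cub1plus": 18 / 43,
        }
    )
    range_scale_by_status: dict = field(
        default_factory=lambda: {
            "solitary": 1.0,
            "cub-of-year": 0.6,
            "cub1plus": 1.2,
        }
    )
    start_date: str = "2004-04-01"
    end_date: str = "2004-11-30"
    max_proposals: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")
        if self.turn_concentration < 0:
            raise ValueError("turn_concentration must be >= 0")
        if abs(sum(self.status_probs.values()) - 1.0) > 1e-9:
            raise ValueError("status_probs must sum to 1")
        lo, hi = self.fixes_per_animal
        if not (0 < lo <= hi):
            raise ValueError("invalid fixes_per_animal range")
        for s, wmap in self.seasonal_preference.items():
            for c, w in wmap.items():
                if not np.isfinite(w):
                    raise ValueError(f"non-finite weight for {c} in season {s}")
        if list(self.season_breaks) != sorted(self.season_breaks):
            raise ValueError("season_breaks must be increasing")


@dataclass
class TruthRecord:
    """Programmed ground truth of a simulation run."""

    seasonal_log_weights: dict  # season_id -> {cover label: weight}
    season_breaks: list
    statuses: dict  # animal_id -> status
    step_scales: dict  # animal_id -> effective step scale

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def generate_landscape(spec: LandscapeSpec) -> CoverRaster:
    """Threshold a smoothed Gaussian random field at target class quantiles.

    ``aggregation`` is the Gaussian smoothing length in cells: 0 gives i.i.d.
    cells, larger values larger patches; quantile thresholding keeps class
    proportions close to target at any aggregation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    field_ = rng.standard_normal((spec.n_rows, spec.n_cols))
    if spec.aggregation > 0:
        field_ = gaussian_filter(field_, sigma=spec.aggregation, mode="wrap")
    props = np.array([spec.target_proportions[c] for c in spec.cover_classes])
    cuts = np.quantile(field_, np.cumsum(props)[:-1]) if len(props) > 1 else []
    codes = np.digitize(field_, cuts).astype(np.int16)
    legend = {i: c for i, c in enumerate(spec.cover_classes)}
    water = [i for i, c in legend.items() if c == "water"]
    return CoverRaster(
        values=codes,
        cell_size=spec.cell_size,
        origin=(0.0, 0.0),
        legend=legend,
        water_code=water[0] if water else None,
    )


def _season_of_week(week: int, breaks: list) -> int:
    return int(np.searchsorted(np.asarray(breaks), week, side="left")) + 1


def simulate_tracks(
    raster: CoverRaster, spec: MovementSpec
) -> tuple[pd.DataFrame, TruthRecord]:
    """Biased correlated random walk over the cover raster.

    The walk advances at ``fix_interval_hours`` over the whole non-denning
    period (start_date..end_date). Per step: turning angle ~ von Mises(0,
    turn_concentration) (uniform when the concentration is 0), step length ~
    gamma(shape 2) with the animal's status-scaled mean, destination accepted
    with probability exp(w_dest - w_max) given the current season's cover
    log-weights; after ``max_proposals`` rejections the last proposal is
    accepted. Positions reflect at the raster boundary.

    A GPS collar misses many scheduled acquisitions, so each animal emits a
    random subset of ``n_fixes`` (drawn from ``fixes_per_animal``) of its
    scheduled locations; the emitted table therefore spans the full season
    range at a nominal 4-h interval with gaps. Returns the fix table
    (animal_id, timestamp, x, y) and the TruthRecord of programmed
    parameters.
    """
    spec.validate()
    if raster.values.size == 0:
        raise ValueError("empty raster")
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = raster.bounds

    label_by_code = raster.legend
    weights_by_season = {}
    for s, wmap in spec.seasonal_preference.items():
        arr = np.zeros(max(label_by_code) + 1)
        for code, label in label_by_code.items():
            arr[code] = wmap.get(label, 0.0)
        weights_by_season[int(s)] = arr
    zero_w = np.zeros(max(label_by_code) + 1)

    status_names = list(spec.status_probs)
    status_p = np.array([spec.status_probs[s] for s in status_names])
    start = pd.Timestamp(spec.start_date)
    end = pd.Timestamp(spec.end_date)
    interval = pd.Timedelta(hours=spec.fix_interval_hours)
    schedule = pd.date_range(start, end, freq=interval)
    n_steps = len(schedule)
    if n_steps < spec.fixes_per_animal[1]:
        raise ValueError(
            "schedule shorter than fixes_per_animal upper bound; "
            "extend end_date or lower the fix count"
        )
    weeks = (1 + (schedule.dayofyear - 1) // 7).to_numpy()

    rows = []
    statuses, step_scales = {}, {}
    for a in range(spec.n_animals):
        animal = f"F{a + 1:02d}"
        status = status_names[rng.choice(len(status_names), p=status_p)]
        scale = spec.step_scale * spec.range_scale_by_status.get(status, 1.0)
        statuses[animal] = status
        step_scales[animal] = scale
        n_fixes = int(rng.integers(spec.fixes_per_animal[0], spec.fixes_per_animal[1] + 1))
        emit = np.zeros(n_steps, bool)
        emit[rng.choice(n_steps, size=n_fixes, replace=False)] = True
        x = rng.uniform(xmin + 0.25 * (xmax - xmin), xmax - 0.25 * (xmax - xmin))
        y = rng.uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))
        heading = rng.uniform(0, 2 * np.pi)
        for i in range(n_steps):
            week = int(weeks[i])
            w = weights_by_season.get(
                _season_of_week(week, spec.season_breaks), zero_w
            )
            wmax = w.max()
            for _ in range(spec.max_proposals):
                if spec.turn_concentration > 0:
                    turn = rng.vonmises(0.0, spec.turn_concentration)
                else:
                    turn = rng.uniform(-np.pi, np.pi)
                new_heading = heading + turn
                length = rng.gamma(2.0, scale / 2.0)
                nx = x + length * np.cos(new_heading)
                ny = y + length * np.sin(new_heading)
                # reflect into bounds
                nx = _reflect(nx, xmin, xmax)
                ny = _reflect(ny, ymin, ymax)
                row = min(int((ny - ymin) // raster.cell_size), raster.n_rows - 1)
                col = min(int((nx - xmin) // raster.cell_size), raster.n_cols - 1)
                if rng.uniform() < np.exp(w[raster.values[row, col]] - wmax):
                    break
            x, y, heading = nx, ny, new_heading
            if emit[i]:
                rows.append((animal, schedule[i], x, y))

    fixes = pd.DataFrame(rows, columns=["animal_id", "timestamp", "x", "y"])
    truth = TruthRecord(
        seasonal_log_weights={
            int(s): dict(w) for s, w in spec.seasonal_preference.items()
        },
        season_breaks=list(spec.season_breaks),
        statuses=statuses,
        step_scales=step_scales,
    )
    return fixes, truth


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return lo + min(v, span * (1 - 1e-12))


def simulate_range_covariates(
    n_animals: int = 29,
    n_ranges: int = 43,
    effects: dict | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a covariate table with known generating model for log10 area.

    Covariate marginals mirror typical field scales (shape indices ~ N(108,
    42) and N(44, 14), proportions in [0, 1], water LSI ~ N(28, 11)).
    ``effects`` maps design columns to coefficients, default a strong
    status + season-1 shape-index model; log10_area = intercept + effects +
    N(0, noise_sd). Animals beyond ``n_animals`` reuse ids (repeat years).
    """
    if effects is None:
        effects = {
            "intercept": 1.6,
            "rs[cub-of-year]": -0.45,
            "rs[cub1plus]": 0.35,
            "s1lsi": 0.01,
        }
    rng = np.random.default_rng(seed)
    animal_ids = [f"F{i + 1:02d}" for i in range(n_animals)]
    ids = [animal_ids[i % n_animals] for i in range(n_ranges)]
    rs = rng.choice(STATUSES, size=n_ranges, p=[19 / 43, 6 / 43, 18 / 43])
    df = pd.DataFrame(
        {
            "animal_id": ids,
            "year": 2003 + (np.arange(n_ranges) // n_animals),
            "rs": rs,
            "s1prop": np.clip(rng.normal(0.37, 0.11, n_ranges), 0.01, 0.99),
            "s1lsi": np.clip(rng.normal(108, 42, n_ranges), 5, None),
            "s1edge": np.clip(rng.normal(92, 16, n_ranges), 1, None),
            "s2prop": np.clip(rng.normal(0.12, 0.14, n_ranges), 0.01, 0.99),
            "s2lsi": np.clip(rng.normal(44, 14, n_ranges), 5, None),
            "s3prop": np.clip(rng.normal(0.15, 0.18, n_ranges), 0.01, 0.99),
            "s3lsi": np.clip(rng.normal(48, 16, n_ranges), 5, None),
            "wlsi": np.clip(rng.normal(28, 11, n_ranges), 5, None),
            "shannon": np.clip(rng.normal(1.47, 0.20, n_ranges), 0.1, None),
        }
    )
    y = np.full(n_ranges, effects.get("intercept", 0.0))
    for name, coef in effects.items():
        if name == "intercept":
            continue
        if name.startswith("rs["):
            lev = name[3:-1]
            y = y + coef * (df["rs"] == lev).to_numpy(float)
        else:
            y = y + coef * df[name].to_numpy(float)
    df["log10_area"] = y + rng.normal(0, noise_sd, n_ranges)
    return df
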