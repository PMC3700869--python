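"""Seasonal use-availability resource selection and its validation.

Selection of cover is modelled by random-effects logistic regression of used
GPS fixes (1) against availability points (0) drawn uniformly inside each
animal's multi-annual 100% MCP at 1 point/km^2, with cover dummies against a
water reference and a per-animal random intercept (design III: the animal is
the unit of replication). The odds-ratio magnitude exp(|beta|) is the relative
selection index (RSI); covers with positive selection and RSI >= 2 are
"highly selected", water is the reference, everything else is matrix. The
reclassified map is validated on held-out fixes with Manly selection ratios
w_s = u_s / a_s and a Wald test of mean w_s = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .geo_io import CoverRaster
from .home_range import RangePolygon
from .mixed_logit import fit_mixed_logit

log = logging.getLogger(__name__)

# selection-map codes
H_CODE, M_CODE, R_CODE = 1, 2, 3
RSI_THRESHOLD = 2.0
CI_MULTIPLIER = 1.96


@dataclass
class CoverEffect:
    """One cover's fitted selection record (one row of the seasonal table)."""

    cover: str
    beta: float
    se: float
    z: float
    ci_lo: float
    ci_hi: float
    wald: float
    p: float
    rsi: float
    use_class: str  # "h" | "m" | "r"
    flag: str | None = None  # "absent" | "separated" | None


@dataclass
class SelectionMap:
    """Cover raster reclassified to highly-selected / matrix / water."""

    values: np.ndarray  # codes H_CODE/M_CODE/R_CODE
    cell_size: float
    origin: tuple[float, float]
    season_id: int | None = None


@dataclass
class SelectionRatioResult:
    """Per-animal Manly selection ratios and the Wald test of mean = 1."""

    season_id: int | None
    animals: list
    u_s: np.ndarray
    a_s: np.ndarray
    w_s: np.ndarray
    mean_w: float
    wald_f: float
    df: tuple[int, int]
    p: float
    excluded: list = field(default_factory=list)


def rsi_from_coefficient(beta: float) -> float:
    """Relative selection index: the odds-ratio magnitude exp(|beta|).

    Avoided covers report the magnitude of avoidance, so RSI >= 1 always;
    reported to one decimal, matching the seasonal selection tables.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return round(float(np.exp(abs(beta))), 1)


def classify_cover(beta: float, rsi: float) -> str:
    """"h" iff positively selected with RSI >= 2; otherwise matrix."""
    return "h" if (beta > 0 and rsi >= RSI_THRESHOLD) else "m"


def sample_availability(
    mcp: RangePolygon | Polygon,
    density: float = 1.0,
    rng: np.random.Generator | None = None,
    min_points: int = 30,
) -> np.ndarray:
    """Uniform random points inside the MCP at ``density`` points per km^2.

    Count = round(area_km2 * density), floored at ``min_points``. Uniformity
    comes from rejection sampling in the polygon's bounding box.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    poly = mcp.geometry if isinstance(mcp, RangePolygon) else mcp
    if poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate polygon")
    rng = rng or np.random.default_rng()
    n = max(int(np.floor(poly.area / 1e6 * density + 0.5)), min_points)
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(int((n - len(out)) * (xmax - xmin) * (ymax - ymin) / poly.area), 64)
        pts = rng.uniform((xmin, ymin), (xmax, ymax), (m, 2))
        keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
    return out[:n]


def train_test_split(
    fixes: pd.DataFrame, ratio: float = 0.80, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal stratified split, round-half-up on the training count.

    Animals with fewer than 5 fixes contribute everything to training (with a
    warning). Deterministic under ``seed``; train and test are disjoint and
    exhaustive.
    """
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for _, sub in fixes.groupby("animal_id", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < 5:
            log.warning("animal with <5 fixes: all to training")
            train_idx.extend(idx)
            continue
        n_train = int(np.floor(ratio * len(idx) + 0.5))
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return fixes.loc[sorted(train_idx)], fixes.loc[sorted(test_idx)]


def fit_rsf(
    used: pd.DataFrame,
    available: pd.DataFrame,
    raster: CoverRaster,
    season_id: int | None = None,
    n_quad: int = 15,
) -> list[CoverEffect]:
    """Random-intercept use-availability logistic fit, water as reference.

    ``used`` and ``available`` need ``animal_id`` and ``cover_code`` columns
    (annotate availability points with :func:`arcrange.geo_io.annotate_fixes`
    first). Covers exhibiting complete separation (all-used or all-available)
    are flagged and dropped from the design; covers in the legend but absent
    from the data are reported as matrix with an "absent" flag. Returns one
    CoverEffect per non-reference cover, sorted by descending coefficient.
    """
    frames = []
    for df, yval in ((used, 1), (available, 0)):
        frames.append(
            pd.DataFrame(
                {
                    "y": yval,
                    "animal_id": df["animal_id"].to_numpy(),
                    "cover_code": df["cover_code"].to_numpy(),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    water = raster.water_code
    present = [c for c in sorted(data["cover_code"].unique()) if c != water]
    if len(present) < 1 or data["cover_code"].nunique() < 2:
        raise ValueError("need at least 2 covers present in the data")

    separated = []
    for c in present:
        ys = data.loc[data["cover_code"] == c, "y"]
        if ys.nunique() < 2:
            separated.append(c)
            log.warning("cover %s completely separated; dropped from fit", c)
    modelled = [c for c in present if c not in separated]

    X = np.column_stack(
        [np.ones(len(data))]
        + [(data["cover_code"] == c).to_numpy(float) for c in modelled]
    )
    names = ["intercept"] + [raster.legend[c] for c in modelled]
    res = fit_mixed_logit(
        data["y"].to_numpy(), X, data["animal_id"].to_numpy(),
        exog_names=names, n_quad=n_quad,
    )

    effects = []
    for j, c in enumerate(modelled, start=1):
        beta, se = float(res.params[j]), float(res.bse[j])
        z = beta / se if se > 0 else np.nan
        rsi = rsi_from_coefficient(beta)
        effects.append(
            CoverEffect(
                cover=raster.legend[c],
                beta=beta,
                se=se,
                z=z,
                ci_lo=beta - CI_MULTIPLIER * se,
                ci_hi=beta + CI_MULTIPLIER * se,
                wald=z * z,
                p=2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                rsi=rsi,
                use_class=classify_cover(beta, rsi),
            )
        )
    for c in separated:
        effects.append(
            CoverEffect(
                cover=raster.legend[c], beta=np.nan, se=np.nan, z=np.nan,
                ci_lo=np.nan, ci_hi=np.nan, wald=np.nan, p=np.nan,
                rsi=np.nan, use_class="m", flag="separated",
            )
        )
    for c in sorted(set(raster.legend) - set(present) - {water}):
        effects.append(
            CoverEffect(
                cover=raster.legend[c], beta=np.nan, se=np.nan, z=np.nan,
                ci_lo=np.nan, ci_hi=np.nan, wald=np.nan, p=np.nan,
                rsi=np.nan, use_class="m", flag="absent",
            )
        )
    effects.sort(key=lambda e: -e.beta if np.isfinite(e.beta) else np.inf)
    if water is not None:
        effects.append(
            CoverEffect(
                cover=raster.legend[water], beta=0.0, se=np.nan, z=np.nan,
                ci_lo=np.nan, ci_hi=np.nan, wald=np.nan, p=np.nan,
                rsi=1.0, use_class="r",
            )
        )
    return effects


def build_selection_map(
    raster: CoverRaster, effects: list[CoverEffect], season_id: int | None = None
) -> SelectionMap:
    """Reclassify the cover raster to highly-selected / matrix / water codes."""
    class_by_label = {e.cover: e.use_class for e in effects}
    out = np.full(raster.values.shape, M_CODE, dtype=np.int16)
    for code, label in raster.legend.items():
        cls = "r" if code == raster.water_code else class_by_label.get(label, "m")
        val = {"h": H_CODE, "m": M_CODE, "r": R_CODE}[cls]
        out[raster.values == code] = val
    return SelectionMap(
        values=out, cell_size=raster.cell_size, origin=raster.origin,
        season_id=season_id,
    )


def effects_table(effects: list[CoverEffect]) -> pd.DataFrame:
    """Seasonal effects as a table mirroring the published column layout."""
    return pd.DataFrame(
        [
            {
                "cover": e.cover, "coeff": e.beta, "se": e.se, "z": e.z,
                "ci_lo": e.ci_lo, "ci_hi": e.ci_hi, "wald": e.wald, "p": e.p,
                "rsi": e.rsi, "use_class": e.use_class,
            }
            for e in effects
        ]
    )


def selection_ratio(
    test_fixes: pd.DataFrame,
    mcps: dict,
    selection_map: SelectionMap,
    season_id: int | None = None,
) -> SelectionRatioResult:
    """Manly selection ratios w_s = u_s / a_s and the Wald test of mean = 1.

    u_s: the animal's fraction of held-out fixes on highly-selected cells;
    a_s: the fraction of cells with centres inside the animal's multi-annual
    MCP that are highly selected. Animals with a_s = 0 are excluded with a
    warning. The test regresses w_s on an intercept and compares the mean to
    1 with an F statistic on (1, n-1) df.
    """
    sm_raster = CoverRaster(
        values=selection_map.values,
        cell_size=selection_map.cell_size,
        origin=selection_map.origin,
        legend={H_CODE: "h", M_CODE: "m", R_CODE: "r"},
        water_code=R_CODE,
    )
    cx, cy = sm_raster.cell_centers()
    animals, u_list, a_list, excluded = [], [], [], []
    for animal, sub in test_fixes.groupby("animal_id", sort=True):
        poly = mcps[animal]
        geom = poly.geometry if isinstance(poly, RangePolygon) else poly
        inside = shapely.contains_xy(geom, cx.ravel(), cy.ravel())
        avail = sm_raster.values.ravel()[inside]
        if len(avail) == 0:
            excluded.append(animal)
            log.warning("animal %s: MCP contains no cell centres; excluded", animal)
            continue
        a = float((avail == H_CODE).mean())
        if a == 0:
            excluded.append(animal)
            log.warning("animal %s: a_s = 0; selection ratio undefined", animal)
            continue
        row, col = sm_raster.cell_index(sub["x"].to_numpy(), sub["y"].to_numpy())
        ok = (row >= 0) & (row < sm_raster.n_rows) & (col >= 0) & (col < sm_raster.n_cols)
        codes = sm_raster.values[row[ok], col[ok]]
        u = float((codes == H_CODE).mean()) if len(codes) else 0.0
        animals.append(animal)
        u_list.append(u)
        a_list.append(a)
    u_arr, a_arr = np.array(u_list), np.array(a_list)
    w = u_arr / a_arr
    n = len(w)
    if n < 2:
        raise ValueError("need at least 2 animals with defined selection ratios")
    mean_w = float(w.mean())
    se = w.std(ddof=1) / np.sqrt(n)
    f = ((mean_w - 1.0) / se) ** 2 if se > 0 else np.inf
    p = float(stats.f.sf(f, 1, n - 1))
    return SelectionRatioResult(
        season_id=season_id,
        animals=animals,
        u_s=u_arr,
        a_s=a_arr,
        w_s=w,
        mean_w=mean_w,
        wald_f=float(f),
        df=(1, n - 1),
        p=p,
        excluded=excluded,
    )
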