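"""Data-driven season definition from bi-weekly cover use.

Seasons are found by Ward's minimum-variance clustering of standardized
bi-weekly cover-use profiles pooled over animals, with the number of clusters
chosen by agreement between the Duda-Hart Je(2)/Je(1) index and the pseudo-t2
statistic. Because Ward clustering ignores time, cluster labels are afterwards
repaired into contiguous blocks of periods (seasons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

log = logging.getLogger(__name__)


@dataclass
class UseProfile:
    """Standardized bi-weekly cover-use matrix (periods x covers).

    ``proportions`` holds the raw per-period cover proportions (rows sum to
    1); ``z`` the per-cover z-scored version actually clustered.
    ``period_weeks`` maps each row to its (first_week, last_week).
    """

    proportions: np.ndarray
    z: np.ndarray
    covers: list
    period_weeks: list[tuple[int, int]]


@dataclass
class SeasonPartition:
    """A contiguous partition of bi-weekly periods into k seasons."""

    k: int
    breaks_week: list[int]  # last week of each season except the final one
    labels: np.ndarray  # season id (1-based) per period
    diagnostics: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"k": self.k, "breaks_week": list(map(int, self.breaks_week))}


def build_profiles(
    fixes: pd.DataFrame, period_weeks: int = 2, min_exposure: float = 0.25
) -> UseProfile:
    """Pooled per-period cover-use proportions, z-scored per cover.

    Period p holds weeks [w0 + p*period_weeks, w0 + (p+1)*period_weeks) where
    w0 is the first observed week. A trailing partial period (the monitoring
    window ends mid-period) is folded into the last full period, and periods
    with zero fixes or with fewer than ``min_exposure`` times the median
    period count are dropped with a warning: truncated or under-sampled
    periods yield use proportions too unstable to cluster. Zero-variance
    covers standardize to an all-zero column.
    """
    if "cover_code" not in fixes or "week_of_year" not in fixes:
        raise ValueError("fixes must be annotated (cover_code, week_of_year)")
    week = fixes["week_of_year"].to_numpy()
    w0 = int(week.min())
    period = (week - w0) // period_weeks
    n_periods = int(period.max()) + 1
    if n_periods < 4:
        raise ValueError("need fixes spanning at least 4 bi-weekly periods")
    covers = sorted(fixes["cover_code"].unique())
    counts = np.zeros((n_periods, len(covers)))
    cover_idx = {c: j for j, c in enumerate(covers)}
    for p, c in zip(period, fixes["cover_code"]):
        counts[p, cover_idx[c]] += 1
    # fold a trailing partial period into the last full one
    last_span_end = w0 + n_periods * period_weeks - 1
    if n_periods > 1 and int(week.max()) < last_span_end:
        counts[-2] += counts[-1]
        counts = counts[:-1]
        n_periods -= 1
    totals = counts.sum(1)
    keep = totals >= max(1.0, min_exposure * np.median(totals[totals > 0]))
    if not keep.all():
        log.warning(
            "build_profiles: dropping %d empty/under-sampled periods",
            (~keep).sum(),
        )
    counts = counts[keep]
    props = counts / counts.sum(1, keepdims=True)
    mu = props.mean(0)
    sd = props.std(0)
    z = np.where(sd > 0, (props - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    period_ids = np.nonzero(keep)[0]
    weeks = [
        (w0 + int(p) * period_weeks, w0 + (int(p) + 1) * period_weeks - 1)
        for p in period_ids
    ]
    if weeks:  # folded trailing period extends to the last observed week
        weeks[-1] = (weeks[-1][0], max(weeks[-1][1], int(week.max())))
    return UseProfile(proportions=props, z=z, covers=covers, period_weeks=weeks)


def _cluster_sse(rows: np.ndarray) -> float:
    """Within-cluster sum of squared deviations about the centroid."""
    return float(((rows - rows.mean(0)) ** 2).sum())


def ward_cluster(profile: UseProfile, k_max: int = 6):
    """Ward linkage on the standardized profile rows.

    Returns (linkage_matrix, candidates, merge_info). ``candidates`` maps k to
    the (temporally unrepaired) cluster labels; ``merge_info`` lists, for each
    merge from latest to earliest, Wishart's objective-function increment and
    the Duda-Hart quantities of the corresponding split (Je(1) of the merged
    cluster, Je(2) summed over its two children, and the merged size n_m).
    """
    X = profile.z
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 periods to cluster")
    Z = linkage(X, method="ward")
    # membership of every internal node, for exact SSE computations
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        merged = members[a] + members[b]
        members[n + m] = merged
        je1 = _cluster_sse(X[merged])
        je2 = _cluster_sse(X[members[a]]) + _cluster_sse(X[members[b]])
        merges.append(
            {
                "je1": je1,
                "je2": je2,
                "n_m": len(merged),
                "objective_increment": je1 - je2,
            }
        )
    candidates = {
        k: fcluster(Z, t=k, criterion="maxclust") for k in range(1, min(k_max, n) + 1)
    }
    return Z, candidates, merges


def _duda_hart_table(merges: list[dict], k_max: int) -> pd.DataFrame:
    """Duda-Hart Je(2)/Je(1) and pseudo-t2 for the split going k -> k+1.

    The split at k clusters is the (k-th from last) merge of the
    agglomeration, read in reverse.
    """
    rows = []
    n_merges = len(merges)
    for k in range(1, min(k_max, n_merges) + 1):
        m = merges[n_merges - k]  # merge undone when moving from k to k+1
        je1, je2, n_m = m["je1"], m["je2"], m["n_m"]
        dh = je2 / je1 if je1 > 0 else 1.0
        if je2 > 0 and n_m > 2:
            t2 = ((je1 - je2) / je2) * (n_m - 2)
        else:
            t2 = np.inf if je1 > je2 else 0.0
        rows.append({"k": k, "duda_hart": dh, "pseudo_t2": t2, "n_m": n_m})
    return pd.DataFrame(rows)


def _force_contiguous(labels: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """Repair cluster labels into k contiguous runs.

    Isolated islands are merged into the neighbouring run whose cluster
    centroid is closer (Euclidean, on the standardized rows); runs are then
    renumbered 1..k in temporal order. While more than k runs remain, the
    shortest run is dissolved into its closer neighbour.
    """
    labels = labels.copy()

    def runs(lab):
        out = []
        start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[start]:
                out.append((start, i, lab[start]))
                start = i
        return out

    centroids = {c: X[labels == c].mean(0) for c in np.unique(labels)}
    r = runs(labels)
    while len(r) > k:
        lengths = [(e - s, idx) for idx, (s, e, _) in enumerate(r)]
        _, idx = min(lengths)
        s, e, _ = r[idx]
        run_mean = X[s:e].mean(0)
        options = []
        if idx > 0:
            options.append(r[idx - 1][2])
        if idx < len(r) - 1:
            options.append(r[idx + 1][2])
        target = min(
            options, key=lambda c: float(((run_mean - centroids[c]) ** 2).sum())
        )
        labels[s:e] = target
        r = runs(labels)
    # renumber in temporal order
    out = np.empty_like(labels)
    for season, (s, e, _) in enumerate(runs(labels), start=1):
        out[s:e] = season
    return out


def choose_k(
    profile: UseProfile, candidates: dict, merges: list[dict], k_max: int = 6
) -> SeasonPartition:
    """Pick k by Duda-Hart / pseudo-t2 agreement and return contiguous seasons.

    The split statistic at k clusters tests whether splitting one of the k
    clusters further is justified: a small Duda-Hart ratio with a large
    pseudo-t2 supports splitting, the reverse supports stopping. Scanning k
    upward, the chosen k is the smallest k (>= 2) where the Duda-Hart ratio
    first turns up and the pseudo-t2 first turns down relative to the split
    before it -- the first simultaneous local extremum of both criteria, with
    ties toward smaller k. If the criteria never agree, the k with the best
    (largest) Duda-Hart is returned with ``diagnostics["agreement"] = False``.
    If every row is identical there is no structure and k = 1.
    """
    table = _duda_hart_table(merges, k_max)
    dh = table["duda_hart"].to_numpy()
    t2 = table["pseudo_t2"].to_numpy()
    if _cluster_sse(profile.z) == 0:
        chosen, agreement = 1, True
    else:
        chosen, agreement = None, True
        for i in range(1, len(table)):
            if dh[i] >= dh[i - 1] and t2[i] <= t2[i - 1]:
                chosen = int(table["k"][i])
                break
        if chosen is None:
            chosen = int(table["k"][int(np.argmax(dh))])
            agreement = False
    labels = _force_contiguous(candidates[chosen], profile.z, chosen)
    k_eff = int(labels.max())
    breaks = [
        profile.period_weeks[i][1]
        for i in range(len(labels) - 1)
        if labels[i + 1] != labels[i]
    ]
    return SeasonPartition(
        k=k_eff,
        breaks_week=breaks,
        labels=labels,
        diagnostics={
            "agreement": agreement,
            "duda_hart": table,
            "objective_increments": [m["objective_increment"] for m in merges],
        },
    )


def define_seasons(fixes: pd.DataFrame, k_max: int = 6) -> SeasonPartition:
    """End-to-end: profiles -> Ward -> k choice -> contiguous seasons."""
    profile = build_profiles(fixes)
    _, candidates, merges = ward_cluster(profile, k_max=k_max)
    return choose_k(profile, candidates, merges, k_max=k_max)
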