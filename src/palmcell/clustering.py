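"""Localization clusterization, cluster typing, and single-molecule time
statistics.

The clusterization proceeds in the stages of the underlying acquisition
protocol: (1) isolate localizations in a region of interest; (2) rasterize
them onto a *virtual pixel* grid much finer (5-10 nm) than the localization
precision (~25 nm) and build the binary occupancy image; (3) label
8-connected components; (4) keep components with at least ``min_events``
localizations and an area larger than one virtual pixel; (5) collect the
member localizations of each surviving object; (6) grow each cluster's
search radius in small steps (10-50 nm) and absorb surrounding events —
including whole neighbouring clusters — whenever the event count in the
enlarged area rises by more than ``growth_frac`` (5%), which keeps large
sparse clusters from being artificially split.

Clusters are then typed: a *PALM-limited* cluster has an apparent FWHM set
by the localization precision and an immobile center of mass; a *dynamic*
cluster is larger and/or moves during the acquisition, representing one or
several diffusing molecules.  Per-cluster time statistics (on/dark times,
duty cycle, cumulative detection curve) certify single-molecule character.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import ParameterError
from .io_core import LocalizationTable

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # Gaussian sigma -> FWHM

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class ClusterParams:
    """Tunable knobs of the clusterization, with field-typical defaults."""

    virtual_pixel_nm: float = 10.0  # typical range 5-10
    min_events: int = 20  # typical range 5-50
    min_area_px: int = 2  # "larger than one virtual pixel"
    merge_step_nm: float = 30.0  # typical range 10-50
    growth_frac: float = 0.05
    include_unclustered_in_growth: bool = True

    def __post_init__(self):
        if min(self.virtual_pixel_nm, self.min_events, self.min_area_px, self.merge_step_nm) <= 0:
            raise ParameterError("all cluster parameters must be positive")
        if not (0 < self.growth_frac < 1):
            raise ParameterError("growth_frac must be in (0, 1)")


@dataclass
class ClusterRecord:
    """One final cluster: membership, geometry, type and time statistics."""

    cluster_id: int
    member_ids: np.ndarray
    centroid_nm: np.ndarray
    n_events: int
    first_frame: int
    last_frame: int
    fwhm_x_nm: float = float("nan")
    fwhm_y_nm: float = float("nan")
    fwhm_nm: float = float("nan")
    fwhm_defined: bool = True
    type: str | None = None  # "palm_limited" | "dynamic"
    time_stats: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# steps 1-4: rasterize, label, filter
# ---------------------------------------------------------------------------

def rasterize_localizations(
    table: LocalizationTable,
    params: ClusterParams,
    roi: tuple[float, float, float, float] | None = None,
):
    """Binary virtual-pixel grid plus a pixel → event-id index.

    ``roi`` is (x0, y0, x1, y1) in nm; defaults to the bounding box of the
    events.  A pixel is set iff at least one localization falls in it under
    the floor convention ``col = floor((x - x0) / virtual_pixel)``.
    Returns (grid, index, origin) where index maps (row, col) to the list
    of member event ids.
    """
    vp = params.virtual_pixel_nm
    if len(table) == 0:
        return np.zeros((0, 0), dtype=bool), {}, (0.0, 0.0)
    xy = table.xy
    ids = table.df["id"].to_numpy()
    if roi is None:
        x0, y0 = xy.min(axis=0)
        x1, y1 = xy.max(axis=0)
    else:
        x0, y0, x1, y1 = roi
        inside = (xy[:, 0] >= x0) & (xy[:, 0] < x1) & (xy[:, 1] >= y0) & (xy[:, 1] < y1)
        xy, ids = xy[inside], ids[inside]
    cols = np.floor((xy[:, 0] - x0) / vp).astype(int)
    rows = np.floor((xy[:, 1] - y0) / vp).astype(int)
    h = int(rows.max()) + 1 if len(rows) else 0
    w = int(cols.max()) + 1 if len(cols) else 0
    grid = np.zeros((h, w), dtype=bool)
    index: dict[tuple[int, int], list[int]] = {}
    for r, c, i in zip(rows, cols, ids):
        grid[r, c] = True
        index.setdefault((int(r), int(c)), []).append(int(i))
    return grid, index, (float(x0), float(y0))


def label_components(grid: np.ndarray) -> tuple[np.ndarray, int]:
    """Label maximal 8-connected components of a binary grid."""
    labeled, n = ndimage.label(grid, structure=EIGHT_CONNECTED)
    return labeled, int(n)


def filter_components(
    labeled: np.ndarray,
    n_labels: int,
    index: dict,
    params: ClusterParams,
) -> tuple[list[dict], list[dict]]:
    """Keep components with enough events and area; log why others fail.

    Returns (candidates, discarded); each candidate dict has ``label``,
    ``pixels`` and ``event_ids``.
    """
    pixels_of: dict[int, list] = {}
    for (r, c) in index:
        lab = int(labeled[r, c])
        if lab > 0:
            pixels_of.setdefault(lab, []).append((r, c))
    candidates, discarded = [], []
    for lab in range(1, n_labels + 1):
        pixels = pixels_of.get(lab, [])
        event_ids = sorted(i for px in pixels for i in index.get(px, []))
        entry = {"label": lab, "pixels": pixels, "event_ids": event_ids}
        reasons = []
        if len(event_ids) < params.min_events:
            reasons.append(f"n_events {len(event_ids)} < {params.min_events}")
        if len(pixels) < params.min_area_px:
            reasons.append(f"area {len(pixels)} px < {params.min_area_px} px")
        if reasons:
            discarded.append({**entry, "reason": "; ".join(reasons)})
        else:
            candidates.append(entry)
    return candidates, discarded


# ---------------------------------------------------------------------------
# step 6: radius-growth merging
# ---------------------------------------------------------------------------

def grow_merge_clusters(
    candidates: list[dict],
    table: LocalizationTable,
    params: ClusterParams,
    roi: tuple[float, float, float, float] | None = None,
) -> list[ClusterRecord]:
    """Merge candidate clusters and stray events by radius growth.

    For each cluster (processed in descending event count, ties broken by
    smallest member id), the envelope radius R is the largest member
    distance from the centroid.  The area is enlarged to R + merge_step;
    if the event count in the enlarged area exceeds the current count by
    more than ``growth_frac``, every event inside — and any whole cluster
    with a captured event — is absorbed, the centroid and R recomputed,
    and the probe repeated.  Otherwise the cluster is finalized.  Every
    event ends up in at most one cluster.
    """
    df = table.df
    pos_of = dict(zip(df["id"].to_numpy(), map(tuple, df[["x_nm", "y_nm"]].to_numpy())))
    frame_of = dict(zip(df["id"].to_numpy(), df["frame"].to_numpy()))

    # pool of probe-able events
    if params.include_unclustered_in_growth:
        pool_ids = df["id"].to_numpy()
        if roi is not None:
            xy = df[["x_nm", "y_nm"]].to_numpy()
            x0, y0, x1, y1 = roi
            inside = (xy[:, 0] >= x0) & (xy[:, 0] < x1) & (xy[:, 1] >= y0) & (xy[:, 1] < y1)
            pool_ids = pool_ids[inside]
    else:
        pool_ids = np.asarray(sorted({i for c in candidates for i in c["event_ids"]}))
    pool_ids = np.asarray(pool_ids, dtype=int)
    pool_xy = np.array([pos_of[i] for i in pool_ids]) if len(pool_ids) else np.empty((0, 2))

    open_clusters = [set(c["event_ids"]) for c in candidates]
    finalized: list[set] = []
    finalized_ids: set[int] = set()

    def _order_key(members: set) -> tuple:
        return (-len(members), min(members))

    while open_clusters:
        open_clusters.sort(key=_order_key)
        members = open_clusters.pop(0)
        while True:
            mem_xy = np.array([pos_of[i] for i in sorted(members)])
            centroid = mem_xy.mean(axis=0)
            radius = float(np.linalg.norm(mem_xy - centroid, axis=1).max())
            probe = radius + params.merge_step_nm
            if len(pool_ids):
                dist = np.linalg.norm(pool_xy - centroid, axis=1)
                inside_mask = dist <= probe
                inside = {int(i) for i in pool_ids[inside_mask]} - finalized_ids
            else:
                inside = set()
            inside |= members
            if len(inside) > len(members) * (1.0 + params.growth_frac):
                new_members = set(inside)
                # absorb whole clusters that have any captured event
                for other in list(open_clusters):
                    if other & new_members:
                        new_members |= other
                        open_clusters.remove(other)
                members = new_members
            else:
                break
        finalized.append(members)
        finalized_ids |= members

    records = []
    for k, members in enumerate(sorted(finalized, key=lambda m: min(m))):
        ids = np.asarray(sorted(members), dtype=int)
        xy = np.array([pos_of[i] for i in ids])
        frames = np.array([frame_of[i] for i in ids])
        records.append(
            ClusterRecord(
                cluster_id=k,
                member_ids=ids,
                centroid_nm=xy.mean(axis=0),
                n_events=len(ids),
                first_frame=int(frames.min()),
                last_frame=int(frames.max()),
            )
        )
    return records


# ---------------------------------------------------------------------------
# per-cluster measurements
# ---------------------------------------------------------------------------

def cluster_fwhm(positions: np.ndarray) -> tuple[float, float, float, bool]:
    """Gaussian-equivalent FWHM = 2*sqrt(2 ln 2) * sample std, per axis.

    Returns (fwhm_x, fwhm_y, mean, defined).  Undefined (flagged) below 2
    events.  The sigma-based estimator is preferred over a histogram
    half-maximum because it stays well-behaved at low event counts.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return float("nan"), float("nan"), float("nan"), False
    sx = positions[:, 0].std(ddof=1)
    sy = positions[:, 1].std(ddof=1)
    fx, fy = FWHM_FACTOR * sx, FWHM_FACTOR * sy
    return float(fx), float(fy), float((fx + fy) / 2), True


def classify_cluster(
    record: ClusterRecord,
    table: LocalizationTable,
    loc_precision_nm: float | None = None,
    mobility_threshold_nm: float | None = None,
    size_factor: float = 1.3,
) -> str:
    """Type a cluster as "palm_limited" or "dynamic".

    PALM-limited requires both a FWHM no larger than ``size_factor`` times
    the precision-limited FWHM (2*sqrt(2 ln 2)*sigma_loc) and a net
    center-of-mass displacement between the first and last temporal thirds
    of its events below ``mobility_threshold_nm`` (default 2*sigma_loc).
    """
    if loc_precision_nm is None:
        loc_precision_nm = table.loc_precision_nm
    if mobility_threshold_nm is None:
        mobility_threshold_nm = 2.0 * loc_precision_nm
    if not record.fwhm_defined or np.isnan(record.fwhm_nm):
        fx, fy, fm, ok = cluster_fwhm(_member_xy(record, table))
        record.fwhm_x_nm, record.fwhm_y_nm, record.fwhm_nm, record.fwhm_defined = fx, fy, fm, ok

    xy = _member_xy(record, table)
    frames = _member_frames(record, table)
    order = np.argsort(frames, kind="stable")
    xy = xy[order]
    n = len(xy)
    third = max(n // 3, 1)
    displacement = float(np.linalg.norm(xy[:third].mean(axis=0) - xy[-third:].mean(axis=0)))

    size_limit = size_factor * FWHM_FACTOR * loc_precision_nm
    small = (record.fwhm_nm <= size_limit) or record.n_events < 2
    immobile = displacement <= mobility_threshold_nm
    record.type = "palm_limited" if (small and immobile) else "dynamic"
    return record.type


def _member_xy(record: ClusterRecord, table: LocalizationTable) -> np.ndarray:
    df = table.df.set_index("id")
    return df.loc[record.member_ids, ["x_nm", "y_nm"]].to_numpy()


def _member_frames(record: ClusterRecord, table: LocalizationTable) -> np.ndarray:
    df = table.df.set_index("id")
    return df.loc[record.member_ids, "frame"].to_numpy()


def event_time_stats(
    record: ClusterRecord,
    table: LocalizationTable,
    n_total_frames: int | None = None,
) -> dict:
    """On/dark time distributions, duty cycle, and cumulative-count linearity.

    On-runs are maximal runs of consecutive frames containing at least one
    member event; dark times are the gaps between them.  The duty cycle is
    the fraction of the full acquisition during which the cluster was 'on'.
    The cumulative detection curve and its linear-fit R² diagnose whether
    photo-activation proceeded at a homogeneous rate.
    """
    frames = np.unique(_member_frames(record, table))
    if n_total_frames is None:
        n_total_frames = int(table.frames.max()) + 1 if len(table) else 1
    breaks = np.flatnonzero(np.diff(frames) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [len(frames) - 1]])
    on_frames = frames[run_ends] - frames[run_starts] + 1
    dark_frames = frames[run_starts[1:]] - frames[run_ends[:-1]] - 1

    ft = table.frame_time_ms
    all_frames = _member_frames(record, table)
    times = np.sort(all_frames) * ft
    cum = np.arange(1, len(times) + 1)
    if len(times) >= 2 and times[-1] > times[0]:
        lin = stats.linregress(times, cum)
        r2 = float(lin.rvalue**2)
    else:
        r2 = float("nan")
    result = {
        "on_times_ms": on_frames * ft,
        "dark_times_ms": dark_frames * ft,
        "duty_cycle": float(len(frames) / n_total_frames),
        "cumulative_times_ms": times,
        "cumulative_counts": cum,
        "linearity_r2": r2,
    }
    record.time_stats = result
    return result


def cluster_motion(
    record: ClusterRecord,
    table: LocalizationTable,
    window_events: int = 10,
) -> dict:
    """Center-of-mass trajectory and MSD of a (dynamic) cluster.

    Member events, ordered in time, are grouped into disjoint windows of
    ``window_events``; each window contributes one CoM position at its mean
    timestamp.  The MSD is averaged over all window pairs at each lag.  For
    a static cluster of spread sigma the MSD flattens at the noise floor
    4*sigma^2/window_events.
    """
    xy = _member_xy(record, table)
    frames = _member_frames(record, table)
    order = np.argsort(frames, kind="stable")
    xy, frames = xy[order], frames[order]
    n_win = len(xy) // window_events
    if n_win < 2:
        return {"com_xy": np.empty((0, 2)), "com_times_ms": np.array([]),
                "msd_nm2": np.array([]), "lags_ms": np.array([]), "flag": "too_few_events"}
    com = np.array(
        [xy[i * window_events : (i + 1) * window_events].mean(axis=0) for i in range(n_win)]
    )
    t = np.array(
        [frames[i * window_events : (i + 1) * window_events].mean() for i in range(n_win)]
    ) * table.frame_time_ms
    lags = np.arange(1, n_win)
    msd = np.array(
        [np.mean(np.sum((com[k:] - com[:-k]) ** 2, axis=1)) for k in lags]
    )
    mean_dt = float(np.mean(np.diff(t))) if n_win > 1 else float("nan")
    return {"com_xy": com, "com_times_ms": t, "msd_nm2": msd,
            "lags_ms": lags * mean_dt, "flag": None}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def find_clusters(
    table: LocalizationTable,
    params: ClusterParams | None = None,
    roi: tuple[float, float, float, float] | None = None,
    classify: bool = True,
) -> list[ClusterRecord]:
    """Run the full clusterization (steps 1-6) and measure each cluster."""
    params = params or ClusterParams()
    grid, index, _origin = rasterize_localizations(table, params, roi)
    labeled, n = label_components(grid)
    candidates, _discarded = filter_components(labeled, n, index, params)
    records = grow_merge_clusters(candidates, table, params, roi)
    for rec in records:
        fx, fy, fm, ok = cluster_fwhm(_member_xy(rec, table))
        rec.fwhm_x_nm, rec.fwhm_y_nm, rec.fwhm_nm, rec.fwhm_defined = fx, fy, fm, ok
        if classify:
            classify_cluster(rec, table)
        event_time_stats(rec, table)
    return records


def clusters_to_json(records: Sequence[ClusterRecord], path) -> None:
    """Full per-cluster detail (membership included) as JSON."""
    import json
    from pathlib import Path

    payload = [
        {
            "cluster_id": r.cluster_id,
            "member_ids": r.member_ids.tolist(),
            "centroid_nm": list(map(float, r.centroid_nm)),
            "n_events": r.n_events,
            "first_frame": r.first_frame,
            "last_frame": r.last_frame,
            "fwhm_x_nm": r.fwhm_x_nm,
            "fwhm_y_nm": r.fwhm_y_nm,
            "fwhm_nm": r.fwhm_nm,
            "fwhm_defined": r.fwhm_defined,
            "type": r.type,
            "duty_cycle": r.time_stats.get("duty_cycle"),
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload))


def clusters_from_json(path) -> list[ClusterRecord]:
    import json
    from pathlib import Path

    out = []
    for d in json.loads(Path(path).read_text()):
        rec = ClusterRecord(
            cluster_id=d["cluster_id"],
            member_ids=np.asarray(d["member_ids"], dtype=int),
            centroid_nm=np.asarray(d["centroid_nm"]),
            n_events=d["n_events"],
            first_frame=d["first_frame"],
            last_frame=d["last_frame"],
            fwhm_x_nm=d["fwhm_x_nm"],
            fwhm_y_nm=d["fwhm_y_nm"],
            fwhm_nm=d["fwhm_nm"],
            fwhm_defined=d["fwhm_defined"],
            type=d["type"],
        )
        if d.get("duty_cycle") is not None:
            rec.time_stats["duty_cycle"] = d["duty_cycle"]
        out.append(rec)
    return out


def clusters_to_frame(records: Sequence[ClusterRecord]):
    """Flat per-cluster summary table (one row per cluster)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_events": r.n_events,
                "centroid_x_nm": r.centroid_nm[0],
                "centroid_y_nm": r.centroid_nm[1],
                "fwhm_x_nm": r.fwhm_x_nm,
                "fwhm_y_nm": r.fwhm_y_nm,
                "fwhm_nm": r.fwhm_nm,
                "first_frame": r.first_frame,
                "last_frame": r.last_frame,
                "type": r.type,
                "duty_cycle": r.time_stats.get("duty_cycle"),
            }
            for r in records
        ]
    )
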