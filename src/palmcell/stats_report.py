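"""Population-level cluster statistics per cell-cycle stage.

Each assigned cluster is projected onto its cell's medial axis; its axial
position is expressed relative to the cell center, normalized by cell
length (0 = midcell, 0.5 = pole; a signed variant in [-0.5, 0.5] is
available by config).  Per stage the module builds the 2D histogram of
cluster FWHM against relative axial distance, the scatter of cluster size
against cell length, and the distribution of localization counts against
axial position — the maps used to read out where and how large protein
assemblies are across the cell cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import CellRecord
from .clustering import ClusterRecord

STAGES = ("vegetative_predivisional", "dividing", "sporulating")


@dataclass
class PopulationStats:
    """Aggregated per-stage cluster maps and summary statistics."""

    per_cluster: pd.DataFrame  # one row per assigned cluster
    histograms: dict = field(default_factory=dict)  # stage -> (H, fwhm_edges, dist_edges)
    summaries: dict = field(default_factory=dict)  # stage -> {mean/sd fwhm, length, n}
    n_assigned: int = 0
    n_orphans: int = 0
    signed: bool = False


def _project_on_axis(axis: np.ndarray, point: np.ndarray) -> float:
    """Arc-length position of the closest point on a polyline to ``point``."""
    seg = np.diff(axis, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d, best_s = np.inf, 0.0
    for i in range(len(seg)):
        L = seg_len[i]
        if L == 0:
            continue
        t = np.clip(np.dot(point - axis[i], seg[i]) / L**2, 0.0, 1.0)
        proj = axis[i] + t * seg[i]
        d = np.linalg.norm(point - proj)
        if d < best_d:
            best_d, best_s = d, cum[i] + t * L
    return best_s


def population_maps(
    cells: list[CellRecord],
    clusters: list[ClusterRecord],
    fwhm_bin_nm: float = 10.0,
    dist_bin: float = 0.05,
    signed: bool = False,
    palm_limited_only: bool = False,
) -> PopulationStats:
    """Build per-stage cluster population maps.

    Requires clusters already assigned to cells and stages classified.
    Unassigned clusters are excluded but counted.
    """
    by_id = {c.cluster_id: c for c in clusters}
    rows = []
    assigned_ids = set()
    for cell in cells:
        axis, L = cell.medial_axis_nm, cell.length_nm
        for cid in cell.cluster_ids:
            cl = by_id.get(cid)
            if cl is None or L <= 0:
                continue
            if palm_limited_only and cl.type not in (None, "palm_limited"):
                continue
            assigned_ids.add(cid)
            s = _project_on_axis(axis, np.asarray(cl.centroid_nm))
            rel = s / L - 0.5
            rows.append(
                {
                    "cluster_id": cid,
                    "cell_id": cell.cell_id,
                    "stage": cell.stage,
                    "fwhm_nm": cl.fwhm_nm,
                    "n_events": cl.n_events,
                    "cell_length_nm": L,
                    "rel_axial_dist": rel if signed else abs(rel),
                    "type": cl.type,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "cell_id", "stage", "fwhm_nm", "n_events",
            "cell_length_nm", "rel_axial_dist", "type",
        ],
    )
    stats = PopulationStats(
        per_cluster=df,
        n_assigned=len(df),
        n_orphans=len([c for c in clusters if c.cluster_id not in assigned_ids]),
        signed=signed,
    )
    dist_lo = -0.5 if signed else 0.0
    for stage in STAGES:
        sub = df[df["stage"] == stage]
        if len(sub):
            fmax = max(float(np.nanmax(sub["fwhm_nm"])), fwhm_bin_nm)
            fwhm_edges = np.arange(0, fmax + fwhm_bin_nm, fwhm_bin_nm)
            dist_edges = np.arange(dist_lo, 0.5 + dist_bin, dist_bin)
            H, fe, de = np.histogram2d(
                sub["fwhm_nm"], sub["rel_axial_dist"], bins=[fwhm_edges, dist_edges]
            )
        else:
            fe = np.arange(0, fwhm_bin_nm * 2, fwhm_bin_nm)
            de = np.arange(dist_lo, 0.5 + dist_bin, dist_bin)
            H = np.zeros((len(fe) - 1, len(de) - 1))
        stats.histograms[stage] = (H, fe, de)
        stats.summaries[stage] = {
            "n_clusters": int(len(sub)),
            "mean_fwhm_nm": float(sub["fwhm_nm"].mean()) if len(sub) else float("nan"),
            "sd_fwhm_nm": float(sub["fwhm_nm"].std(ddof=1)) if len(sub) > 1 else float("nan"),
            "mean_length_nm": float(sub["cell_length_nm"].mean()) if len(sub) else float("nan"),
            "sd_length_nm": float(sub["cell_length_nm"].std(ddof=1)) if len(sub) > 1 else float("nan"),
            "mean_n_events": float(sub["n_events"].mean()) if len(sub) else float("nan"),
        }
    return stats


def save_report(stats: PopulationStats, outdir: str | Path, plots: bool = True) -> dict:
    """Write CSV tables (and optional PNG maps) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "clusters_per_stage.csv"
    stats.per_cluster.to_csv(p, index=False)
    paths["per_cluster"] = p
    summary = pd.DataFrame(stats.summaries).T
    p = outdir / "stage_summaries.csv"
    summary.to_csv(p)
    paths["summaries"] = p
    for stage, (H, fe, de) in stats.histograms.items():
        p = outdir / f"hist_{stage}.csv"
        pd.DataFrame(
            H,
            index=pd.Index(fe[:-1], name="fwhm_nm_low"),
            columns=[f"{d:.3f}" for d in de[:-1]],
        ).to_csv(p)
        paths[f"hist_{stage}"] = p
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(stats.histograms), figsize=(4 * len(stats.histograms), 3.2))
        axes = np.atleast_1d(axes)
        for ax, (stage, (H, fe, de)) in zip(axes, stats.histograms.items()):
            ax.imshow(
                H, origin="lower", aspect="auto",
                extent=[de[0], de[-1], fe[0], fe[-1]],
            )
            ax.set_xlabel("relative axial distance")
            ax.set_ylabel("FWHM (nm)")
            ax.set_title(stage.replace("_", "/"))
        fig.tight_layout()
        p = outdir / "population_maps.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["plot"] = p
    return paths
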