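"""Fiducial-based lateral drift estimation, QC and correction.

The workflow mirrors standard fiducial-mark practice: bead localizations
are linked into per-bead tracks, each track is re-zeroed to its first valid
frame, and the reference drift trajectory is the per-frame mean over the
selected tracks.  Quality control subtracts the reference from every track
and computes per-bead residual standard deviations along x and y; the
correction is accepted only when the worst bead/axis residual stays below
a threshold (default 10 nm).  On homogeneous fields (e.g. cells bound to a
functionalized coverslip in a flow chamber) all beads share one trajectory
and the residual is set by localization noise alone; on agarose pads,
local matrix rearrangement adds independent per-bead motion that this QC
is designed to catch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import CoverageError, GapError, ParameterError
from .io_core import LocalizationTable

DEFAULT_RESIDUAL_THRESHOLD_NM = 10.0


@dataclass
class FiducialTrack:
    """Per-frame positions of one bead; NaN rows mark missed frames."""

    bead_id: int
    positions: np.ndarray  # (n_frames, 2), NaN where invalid

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ParameterError("positions must be (n_frames, 2)")
        if self.valid.sum() < 2:
            raise ParameterError("a fiducial track needs >= 2 valid frames")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.positions).all(axis=1)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def interpolated(self) -> np.ndarray:
        """Positions with interior gaps linearly interpolated (no extrapolation)."""
        pos = self.positions.copy()
        v = self.valid
        idx = np.arange(len(pos))
        for ax in (0, 1):
            pos[~v, ax] = np.interp(idx[~v], idx[v], pos[v, ax])
        first, last = idx[v][0], idx[v][-1]
        pos[:first] = np.nan
        pos[last + 1 :] = np.nan
        return pos

    def rezeroed(self) -> np.ndarray:
        """Interpolated positions relative to the first valid frame."""
        pos = self.interpolated()
        first = np.flatnonzero(np.isfinite(pos).all(axis=1))[0]
        return pos - pos[first]


@dataclass
class DriftModel:
    """Reference drift trajectory plus per-bead residual QC."""

    reference: np.ndarray  # (n_frames, 2), reference[0] == (0, 0)
    beads_used: list[int] = field(default_factory=list)
    sigma_x: dict[int, float] = field(default_factory=dict)
    sigma_y: dict[int, float] = field(default_factory=dict)
    accepted: bool | None = None
    threshold_nm: float = DEFAULT_RESIDUAL_THRESHOLD_NM

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.ndim != 2 or self.reference.shape[1] != 2:
            raise ParameterError("reference must be (n_frames, 2)")
        if not np.allclose(self.reference[0], 0.0, atol=1e-9):
            raise ParameterError("reference trajectory must start at (0, 0)")

    @property
    def n_frames(self) -> int:
        return len(self.reference)

    @property
    def max_residual_nm(self) -> float:
        vals = list(self.sigma_x.values()) + list(self.sigma_y.values())
        return float(max(vals)) if vals else float("nan")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "reference": self.reference.tolist(),
            "beads_used": self.beads_used,
            "sigma_x": {str(k): v for k, v in self.sigma_x.items()},
            "sigma_y": {str(k): v for k, v in self.sigma_y.items()},
            "accepted": self.accepted,
            "threshold_nm": self.threshold_nm,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DriftModel":
        d = json.loads(Path(path).read_text())
        return cls(
            reference=np.asarray(d["reference"]),
            beads_used=list(d["beads_used"]),
            sigma_x={int(k): v for k, v in d["sigma_x"].items()},
            sigma_y={int(k): v for k, v in d["sigma_y"].items()},
            accepted=d["accepted"],
            threshold_nm=d["threshold_nm"],
        )


# ---------------------------------------------------------------------------

def link_fiducials(bead_locs: LocalizationTable, max_jump_nm: float = 500.0) -> list[FiducialTrack]:
    """Link per-frame bead localizations into tracks by nearest neighbor.

    Frame-to-frame assignments are globally optimal (Hungarian algorithm on
    the distance matrix); any link longer than ``max_jump_nm`` is broken and
    the localization starts a new track.  Each localization joins at most
    one track.
    """
    if len(bead_locs) == 0:
        return []
    df = bead_locs.df
    n_frames = int(df["frame"].max()) + 1
    tracks: list[dict] = []  # {'pos': {frame: (x, y)}, 'last': (x, y), 'last_frame': int}
    by_frame = {f: g[["x_nm", "y_nm"]].to_numpy() for f, g in df.groupby("frame")}

    active: list[dict] = []
    for f in range(n_frames):
        pts = by_frame.get(f)
        if pts is None or len(pts) == 0:
            continue
        assigned = np.zeros(len(pts), dtype=bool)
        if active:
            last = np.array([t["last"] for t in active])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            rows, cols = linear_sum_assignment(dist)
            for r, c in zip(rows, cols):
                if dist[r, c] <= max_jump_nm:
                    active[r]["pos"][f] = pts[c]
                    active[r]["last"] = pts[c]
                    assigned[c] = True
        for c in np.flatnonzero(~assigned):
            t = {"pos": {f: pts[c]}, "last": pts[c]}
            active.append(t)
            tracks.append(t)

    out = []
    bead_id = 0
    for t in tracks:
        if len(t["pos"]) < 2:
            continue
        pos = np.full((n_frames, 2), np.nan)
        for f, p in t["pos"].items():
            pos[f] = p
        out.append(FiducialTrack(bead_id=bead_id, positions=pos))
        bead_id += 1
    # deterministic ordering: by first-frame position (x, then y)
    def _key(tr: FiducialTrack):
        first = np.flatnonzero(tr.valid)[0]
        return (first, tr.positions[first, 0], tr.positions[first, 1])

    out.sort(key=_key)
    for i, tr in enumerate(out):
        tr.bead_id = i
    return out


def estimate_mean_drift(
    tracks: list[FiducialTrack],
    selection: list[int] | None = None,
) -> DriftModel:
    """Mean-trajectory drift model over the selected beads.

    Each selected track is re-zeroed to its first valid frame; the reference
    trajectory is the per-frame mean of the re-zeroed tracks, itself
    re-zeroed to frame 0.  All frames must be covered by at least one
    selected bead.
    """
    if selection is None:
        selection = [t.bead_id for t in tracks]
    if not selection:
        raise ParameterError("bead selection is empty")
    sel = [t for t in tracks if t.bead_id in set(selection)]
    if not sel:
        raise ParameterError("no tracks match the selection")
    n_frames = max(t.n_frames for t in sel)
    stack = np.full((len(sel), n_frames, 2), np.nan)
    for i, t in enumerate(sel):
        z = t.rezeroed()
        stack[i, : len(z)] = z
    counts = np.isfinite(stack[:, :, 0]).sum(axis=0)
    if (counts == 0).any():
        f = int(np.flatnonzero(counts == 0)[0])
        raise GapError(f"no valid bead observation at frame {f}", frame=f)
    with np.errstate(invalid="ignore"):
        reference = np.nanmean(stack, axis=0)
    reference = reference - reference[0]
    return DriftModel(reference=reference, beads_used=[t.bead_id for t in sel])


def drift_residuals(
    tracks: list[FiducialTrack],
    model: DriftModel,
    threshold_nm: float = DEFAULT_RESIDUAL_THRESHOLD_NM,
) -> DriftModel:
    """Fill per-bead residual sigmas and the accepted flag on ``model``.

    The residual of a bead is its re-zeroed track minus the reference; the
    model is accepted when the largest residual standard deviation over the
    used beads and both axes is below ``threshold_nm``.
    """
    used = set(model.beads_used)
    sigma_x, sigma_y = {}, {}
    for t in tracks:
        if t.bead_id not in used:
            continue
        if t.n_frames > model.n_frames:
            raise CoverageError("model does not cover all track frames")
        z = t.rezeroed()
        res = z - model.reference[: len(z)]
        ok = np.isfinite(res).all(axis=1)
        sigma_x[t.bead_id] = float(np.std(res[ok, 0]))
        sigma_y[t.bead_id] = float(np.std(res[ok, 1]))
    model.sigma_x = sigma_x
    model.sigma_y = sigma_y
    model.threshold_nm = threshold_nm
    vals = list(sigma_x.values()) + list(sigma_y.values())
    model.accepted = bool(vals and max(vals) < threshold_nm)
    return model


def select_nearest_beads(
    tracks: list[FiducialTrack], point_nm: tuple[float, float], n: int = 7
) -> list[int]:
    """Ids of the n tracks nearest to a point (mean valid position), ties by id.

    Used in the agarose-pad workflow where each cell is corrected with its
    closest fiducials; homogeneous fields simply use all accepted beads.
    """
    p = np.asarray(point_nm, dtype=float)
    scored = []
    for t in tracks:
        mean = np.nanmean(t.positions, axis=0)
        scored.append((float(np.linalg.norm(mean - p)), t.bead_id))
    scored.sort()
    return [bid for _, bid in scored[:n]]


def apply_drift(
    table: LocalizationTable, model: DriftModel, override: bool = False
) -> LocalizationTable:
    """Subtract the reference trajectory from every localization.

    Requires an accepted model unless ``override`` is set; every event frame
    must lie inside the model's range.
    """
    if model.accepted is False and not override:
        raise ParameterError("drift model was rejected by QC; pass override=True to force")
    if len(table) == 0:
        return table.with_df(table.df.copy())
    frames = table.frames
    if frames.max() >= model.n_frames or frames.min() < 0:
        raise CoverageError(
            f"model covers frames [0, {model.n_frames - 1}] but table has frame {frames.max()}"
        )
    df = table.df.copy()
    df["x_nm"] = df["x_nm"].to_numpy() - model.reference[frames, 0]
    df["y_nm"] = df["y_nm"].to_numpy() - model.reference[frames, 1]
    out = table.with_df(df)
    out.meta = dict(table.meta, drift_corrected=True)
    return out
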