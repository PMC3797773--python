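"""Ground-truthed synthetic acquisitions.

Every generator is deterministic under a fixed seed and returns, alongside
the simulated data, a machine-readable ``truth`` dictionary that fully
determines the expected result of the pipeline stage it exercises:

* drifting fiducial bead tracks (homogeneous chamber vs agarose-pad modes),
* two-channel bead fields related by a known second-order polynomial,
* blinking-emitter localization fields forming static / dynamic clusters,
* spherocylindrical bacterial cells with membrane + DNA images, septa,
  and optional out-of-plane tilt rendered across z-planes.

The blinking model is deliberately minimal: each photo-activated emitter
occupies one contiguous on-window of 1-3 frames, windows never overlap
within a cluster, so every frame contains at most one event per
diffraction-limited area — the regime a well-tuned acquisition targets.
Full photophysics (triplet shelving, bleaching kinetics) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationError, ParameterError
from .io_core import ImageStack, LocalizationTable

# 10-minute acquisition at the default 50 ms frame time
AGAROSE_PRESET = {"mode": "agarose", "total_drift_nm": 200.0, "anomaly_nm": 50.0}
AGAROSE_PRESET_N_FRAMES = 12000


# ---------------------------------------------------------------------------
# fiducial bead tracks
# ---------------------------------------------------------------------------

def _common_drift_curve(n_frames: int, total_drift_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Linear ramp + seeded random walk, rescaled to a net |displacement| of
    ``total_drift_nm`` over the acquisition."""
    if total_drift_nm == 0:
        return np.zeros((n_frames, 2))
    theta = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(theta), np.sin(theta)])
    t = np.linspace(0.0, 1.0, n_frames)
    linear = np.outer(t, direction) * 0.6 * total_drift_nm
    walk = np.cumsum(rng.normal(0.0, 1.0, size=(n_frames, 2)), axis=0)
    walk -= walk[0]
    span = np.abs(walk).max() or 1.0
    walk *= 0.4 * total_drift_nm / span
    curve = linear + walk
    net = np.linalg.norm(curve[-1])
    if net > 0:
        curve *= total_drift_nm / net
    return curve - curve[0]


def gen_bead_tracks(
    n_beads: int,
    n_frames: int,
    drift_spec: dict | None = None,
    noise_nm: float = 5.0,
    seed: int = 0,
    field_size_nm: tuple[float, float] = (50_000.0, 50_000.0),
    frame_time_ms: float = 50.0,
) -> tuple[LocalizationTable, dict]:
    """Simulate fiducial bead localizations per frame.

    ``drift_spec`` keys: ``mode`` ("homogeneous" or "agarose"),
    ``total_drift_nm`` (net common drift over the acquisition),
    ``anomaly_nm`` (agarose only: per-bead independent walk scale).
    Homogeneous mode models a microfluidics chamber where all beads follow
    one common trajectory; agarose mode adds anomalous per-bead motion from
    local matrix rearrangement.
    """
    if n_beads < 1:
        raise ParameterError("n_beads must be >= 1")
    if noise_nm < 0:
        raise ParameterError("noise_nm must be >= 0")
    spec = dict(drift_spec or {"mode": "homogeneous", "total_drift_nm": 200.0})
    mode = spec.get("mode", "homogeneous")
    total = float(spec.get("total_drift_nm", 200.0))
    anomaly = float(spec.get("anomaly_nm", 0.0))
    if total < 0 or anomaly < 0:
        raise ParameterError("drift scales must be >= 0")

    rng = np.random.default_rng(seed)
    base = rng.uniform([0, 0], field_size_nm, size=(n_beads, 2))
    drift = _common_drift_curve(n_frames, total, rng)

    anomalies = np.zeros((n_beads, n_frames, 2))
    if mode == "agarose" and anomaly > 0:
        steps = rng.normal(0.0, anomaly / math.sqrt(n_frames), size=(n_beads, n_frames, 2))
        anomalies = np.cumsum(steps, axis=1)
        anomalies -= anomalies[:, :1, :]

    noise = rng.normal(0.0, noise_nm, size=(n_beads, n_frames, 2)) if noise_nm > 0 else 0.0
    pos = base[:, None, :] + drift[None, :, :] + anomalies + noise

    frames = np.repeat(np.arange(n_frames), n_beads)
    bead_idx = np.tile(np.arange(n_beads), n_frames)
    xy = pos[bead_idx, frames]
    table = LocalizationTable.from_arrays(
        frame=frames,
        x_nm=xy[:, 0],
        y_nm=xy[:, 1],
        intensity=np.full(len(frames), 1000.0),
        channel="beads",
        ids=np.arange(len(frames)),
        frame_time_ms=frame_time_ms,
    )
    truth = {
        "mode": mode,
        "base_positions": base,
        "drift": drift,
        "anomalies": anomalies,
        "noise_nm": noise_nm,
        "bead_of_id": bead_idx[np.argsort(frames, kind="stable")],
    }
    # ids were assigned in (frame, bead) order already sorted by frame
    truth["bead_of_id"] = bead_idx
    return table, truth


# ---------------------------------------------------------------------------
# two-channel bead fields (registration)
# ---------------------------------------------------------------------------

POLY2_TERMS = ("1", "x", "y", "x2", "xy", "y2")


def poly2_eval(coeffs: Sequence[float], points: np.ndarray) -> np.ndarray:
    """Evaluate a 6-term second-order polynomial (basis 1, x, y, x², xy, y²)."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (6,):
        raise ParameterError("expected exactly 6 coefficients (basis 1, x, y, x², xy, y²)")
    x, y = points[:, 0], points[:, 1]
    return c[0] + c[1] * x + c[2] * y + c[3] * x * x + c[4] * x * y + c[5] * y * y


def make_polynomial_coeffs(
    translation_nm: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    magnification: float = 1.0,
    quadratic: float = 0.0,
) -> dict:
    """Build per-axis coefficient sets for a rigid+scale transform with an
    optional uniform quadratic distortion (same coefficient on x², xy, y²)."""
    a = math.radians(rotation_deg)
    m = magnification
    cx = [translation_nm[0], m * math.cos(a), -m * math.sin(a), quadratic, quadratic, quadratic]
    cy = [translation_nm[1], m * math.sin(a), m * math.cos(a), quadratic, quadratic, quadratic]
    return {"x": cx, "y": cy}


def identity_coeffs() -> dict:
    return {"x": [0, 1, 0, 0, 0, 0], "y": [0, 0, 1, 0, 0, 0]}


def gen_channel_pair(
    n_beads: int,
    transform_coeffs: dict,
    noise_nm: float = 3.0,
    seed: int = 0,
    field_size_nm: tuple[float, float] = (50_000.0, 50_000.0),
) -> tuple[LocalizationTable, LocalizationTable, dict]:
    """Two bead tables related by a known second-order polynomial warp.

    Channel B positions are the polynomial image of channel A truth
    positions; both observed tables carry iid Gaussian localization noise.
    """
    for axis in ("x", "y"):
        if axis not in transform_coeffs or len(transform_coeffs[axis]) != 6:
            raise ParameterError("transform_coeffs needs 6 coefficients per axis")
    if noise_nm < 0:
        raise ParameterError("noise_nm must be >= 0")
    rng = np.random.default_rng(seed)
    true_a = rng.uniform([0, 0], field_size_nm, size=(n_beads, 2))
    true_b = np.column_stack(
        [poly2_eval(transform_coeffs["x"], true_a), poly2_eval(transform_coeffs["y"], true_a)]
    )
    obs_a = true_a + (rng.normal(0, noise_nm, true_a.shape) if noise_nm > 0 else 0.0)
    obs_b = true_b + (rng.normal(0, noise_nm, true_b.shape) if noise_nm > 0 else 0.0)

    def _table(xy):
        return LocalizationTable.from_arrays(
            frame=np.zeros(n_beads, dtype=int),
            x_nm=xy[:, 0],
            y_nm=xy[:, 1],
            intensity=np.full(n_beads, 1000.0),
            channel="beads",
            ids=np.arange(n_beads),
        )

    truth = {"true_a": true_a, "true_b": true_b, "coeffs": transform_coeffs, "noise_nm": noise_nm}
    return _table(obs_a), _table(obs_b), truth


# ---------------------------------------------------------------------------
# blinking-emitter localization fields (clustering)
# ---------------------------------------------------------------------------

def _blink_schedule(n_events: int, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Frame indices for ``n_events`` localizations: contiguous on-runs of
    1-3 frames separated by >= 1 dark frame, in temporal order."""
    run_lengths: list[int] = []
    remaining = n_events
    while remaining > 0:
        r = int(rng.integers(1, 4))
        r = min(r, remaining)
        run_lengths.append(r)
        remaining -= r
    n_runs = len(run_lengths)
    on_frames = n_events
    min_needed = on_frames + n_runs - 1
    if n_frames < min_needed:
        raise GenerationError(
            f"cannot schedule {n_events} events in {n_frames} frames "
            f"(needs >= {min_needed} with dark gaps)"
        )
    spare = n_frames - min_needed
    # distribute spare dark frames over the n_runs + 1 gap slots
    extra = rng.multinomial(spare, np.full(n_runs + 1, 1.0 / (n_runs + 1)))
    frames = []
    cursor = int(extra[0])
    for i, r in enumerate(run_lengths):
        frames.extend(range(cursor, cursor + r))
        cursor += r + 1 + int(extra[i + 1])
    return np.asarray(frames[:n_events], dtype=int)


def _polyline_points(path: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Points at normalized arc-length positions ``s`` along a polyline."""
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    cum = np.concatenate([[0.0], np.cumsum(seg_len)]) / (total or 1.0)
    out = np.empty((len(s), 2))
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] / (total or 1.0) > 0, seg_len[idx] / (total or 1.0), 1.0)
    out = path[idx] + seg[idx] * np.clip(frac, 0, 1)[:, None]
    return out


def gen_localization_field(
    cluster_specs: Sequence[dict],
    seed: int = 0,
    n_frames: int = 2000,
    field_size_nm: tuple[float, float] = (4000.0, 4000.0),
    frame_time_ms: float = 50.0,
    loc_precision_nm: float = 25.0,
) -> tuple[LocalizationTable, dict]:
    """Blinking-emitter field with known cluster membership.

    Each spec dict has ``kind`` in {"static", "dynamic", "noise"}:

    * static — ``center``, ``sigma_nm``, ``n_events``: isotropic Gaussian
      scatter around a fixed center (a PALM-limited assembly).
    * dynamic — ``path`` (list of waypoints, nm), ``sigma_nm`` (jitter),
      ``n_events``: events placed along the path in temporal order.
    * noise — ``n_events``, ``clearance_nm``: isolated single events at
      least the clearance away from every cluster envelope.
    """
    rng = np.random.default_rng(seed)
    rows_frame, rows_x, rows_y, labels = [], [], [], []
    schedules: list[np.ndarray] = []
    envelopes: list[tuple[np.ndarray, float]] = []  # (bbox points, pad) for clearance

    cluster_idx = 0
    for spec in cluster_specs:
        kind = spec["kind"]
        if kind == "noise":
            continue
        n = int(spec["n_events"])
        if n < 1:
            raise ParameterError("n_events must be >= 1")
        sigma = float(spec.get("sigma_nm", 15.0))
        frames = _blink_schedule(n, n_frames, rng)
        if kind == "static":
            center = np.asarray(spec["center"], dtype=float)
            pts = center + rng.normal(0, sigma, size=(n, 2))
            envelopes.append((center[None, :], 6 * sigma))
        elif kind == "dynamic":
            path = np.asarray(spec["path"], dtype=float)
            if path.ndim != 2 or len(path) < 2:
                raise ParameterError("dynamic path needs >= 2 waypoints")
            s = np.linspace(0.0, 1.0, n)
            pts = _polyline_points(path, s) + rng.normal(0, sigma, size=(n, 2))
            envelopes.append((path, 6 * sigma))
        else:
            raise ParameterError(f"unknown cluster kind {kind!r}")
        rows_frame.append(frames)
        rows_x.append(pts[:, 0])
        rows_y.append(pts[:, 1])
        labels.append(np.full(n, cluster_idx))
        schedules.append(frames)
        cluster_idx += 1

    # noise events, rejection-sampled against all cluster envelopes
    for spec in cluster_specs:
        if spec["kind"] != "noise":
            continue
        n = int(spec["n_events"])
        clearance = float(spec.get("clearance_nm", 500.0))
        pts = np.empty((n, 2))
        placed = 0
        tries = 0
        while placed < n:
            tries += 1
            if tries > 10000 * max(n, 1):
                raise GenerationError("cannot place noise events at the requested clearance")
            p = rng.uniform([0, 0], field_size_nm)
            ok = True
            for anchor, pad in envelopes:
                d = np.linalg.norm(anchor - p, axis=1).min()
                if d < clearance + pad:
                    ok = False
                    break
            if ok:
                pts[placed] = p
                placed += 1
        frames = rng.integers(0, n_frames, size=n)
        rows_frame.append(frames)
        rows_x.append(pts[:, 0])
        rows_y.append(pts[:, 1])
        labels.append(np.full(n, -1))

    if rows_frame:
        frame = np.concatenate(rows_frame)
        x = np.concatenate(rows_x)
        y = np.concatenate(rows_y)
        lab = np.concatenate(labels)
    else:
        frame = x = y = lab = np.array([])
    ids = np.arange(len(frame), dtype=int)
    table = LocalizationTable.from_arrays(
        frame=frame.astype(int),
        x_nm=x,
        y_nm=y,
        intensity=np.full(len(frame), 500.0),
        channel="palm",
        ids=ids,
        frame_time_ms=frame_time_ms,
        loc_precision_nm=loc_precision_nm,
    )
    truth = {
        "label_of_id": {int(i): int(l) for i, l in zip(ids, lab)},
        "n_clusters": cluster_idx,
        "specs": list(cluster_specs),
        "schedules": schedules,
        "n_frames": n_frames,
    }
    return table, truth


def gen_demo_field(seed: int = 3) -> tuple[LocalizationTable, dict]:
    """The canonical two-cluster demonstration field.

    One PALM-limited cluster (immobile, precision-sized), one dynamic
    cluster moving ~900 nm along a path, and a handful of isolated noise
    events: the textbook case the clusterization should resolve into
    exactly two clusters.
    """
    specs = [
        {"kind": "static", "center": (1000.0, 1000.0), "sigma_nm": 20.0, "n_events": 150},
        {"kind": "dynamic", "path": [(2500.0, 2500.0), (3300.0, 2900.0)],
         "sigma_nm": 15.0, "n_events": 400},
        {"kind": "noise", "n_events": 8, "clearance_nm": 400.0},
    ]
    return gen_localization_field(specs, seed=seed, n_frames=2000)


# ---------------------------------------------------------------------------
# bacterial cell scenes (membrane + DNA images)
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """Geometry and rendering parameters of one spherocylindrical cell.

    Lengths in nm. ``septum_rel_pos`` is the septum position as a fraction
    of cell length from the left pole (None = no septum);
    ``septum_openness`` in [0, 1] is the relative radius of the unclosed
    central hole (0 = fully closed disc). ``tilt_deg`` tips the long axis
    out of the imaging plane; ``angle_deg`` rotates it within the plane.
    """

    length_nm: float = 3000.0
    width_nm: float = 800.0
    septum_rel_pos: float | None = None
    septum_openness: float = 0.0
    tilt_deg: float = 0.0
    angle_deg: float = 0.0
    center_nm: tuple[float, float] | None = None
    membrane_intensity: float = 1000.0
    background: float = 100.0
    noise_sigma: float = 10.0

    def __post_init__(self):
        if not (0 < self.width_nm < self.length_nm):
            raise ParameterError("need 0 < width < length")
        if not (-90 <= self.tilt_deg <= 90):
            raise ParameterError("tilt_deg must be within [-90, 90]")
        if self.septum_rel_pos is not None and not (0 <= self.septum_rel_pos <= 1):
            raise ParameterError("septum_rel_pos must be in [0, 1]")
        if not (0 <= self.septum_openness <= 1):
            raise ParameterError("septum_openness must be in [0, 1]")

    @property
    def stage(self) -> str:
        """Ground-truth cell-cycle stage implied by the septum geometry."""
        if self.septum_rel_pos is None:
            return "vegetative_predivisional"
        if 1 / 3 <= self.septum_rel_pos <= 2 / 3:
            return "dividing"
        return "sporulating"

    def contour(self, n_points: int = 64) -> np.ndarray:
        """Closed stadium-shaped outline polygon in field coordinates (nm)."""
        L, R = self.length_nm, self.width_nm / 2
        h = L / 2 - R
        n_cap = max(n_points // 4, 4)
        n_side = max(n_points // 4, 4)
        t = np.linspace(-np.pi / 2, np.pi / 2, n_cap)
        right = np.column_stack([h + R * np.cos(t), R * np.sin(t)])
        top = np.column_stack([np.linspace(h, -h, n_side), np.full(n_side, R)])
        t2 = np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap)
        left = np.column_stack([-h + R * np.cos(t2), R * np.sin(t2)])
        bottom = np.column_stack([np.linspace(-h, h, n_side), np.full(n_side, -R)])
        pts = np.vstack([right, top, left, bottom])
        a = math.radians(self.angle_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        c = np.asarray(self.center_nm if self.center_nm is not None else (0.0, 0.0))
        return pts @ rot.T + c


def _cell_frame_coords(spec: CellSpec, X: np.ndarray, Y: np.ndarray, z: float):
    """Map field coords at plane height z to the cell body frame (u, v, w)."""
    cx, cy = spec.center_nm
    a = math.radians(spec.angle_deg)
    px, py = X - cx, Y - cy
    u0 = px * math.cos(a) + py * math.sin(a)
    v = -px * math.sin(a) + py * math.cos(a)
    t = math.radians(spec.tilt_deg)
    u = u0 * math.cos(t) + z * math.sin(t)
    w = -u0 * math.sin(t) + z * math.cos(t)
    return u, v, w


def _render_cell(spec: CellSpec, X, Y, z, psf_sigma_nm):
    u, v, w = _cell_frame_coords(spec, X, Y, z)
    R = spec.width_nm / 2
    h = spec.length_nm / 2 - R
    ucl = np.clip(u, -h, h)
    d_axis = np.sqrt((u - ucl) ** 2 + v**2 + w**2)
    membrane = spec.membrane_intensity * np.exp(-((d_axis - R) ** 2) / (2 * psf_sigma_nm**2))
    if spec.septum_rel_pos is not None:
        u_s = (spec.septum_rel_pos - 0.5) * spec.length_nm
        r = np.sqrt(v**2 + w**2)
        annulus = (r <= R) & (r >= spec.septum_openness * R)
        ridge = (
            spec.membrane_intensity
            * (1.0 - spec.septum_openness)
            * np.exp(-((u - u_s) ** 2) / (2 * psf_sigma_nm**2))
        )
        membrane = membrane + np.where(annulus, ridge, 0.0)

    # nucleoids: two flanking blobs when a septum exists, one central
    # otherwise; blobs overlap axially so each cell yields one DNA object
    dna = np.zeros_like(membrane)
    if spec.septum_rel_pos is None:
        blob_u, su = [0.0], spec.length_nm / 5
    else:
        blob_u, su = [-0.25 * spec.length_nm, 0.25 * spec.length_nm], spec.length_nm / 6
    sv = R / 1.8
    for bu in blob_u:
        dna += 0.8 * spec.membrane_intensity * np.exp(
            -((u - bu) ** 2) / (2 * su**2) - v**2 / (2 * sv**2) - w**2 / (2 * sv**2)
        )
    return membrane, dna


def gen_cell_scene(
    cell_specs: Sequence[CellSpec],
    pixel_size_nm: float = 110.0,
    psf_sigma_nm: float = 120.0,
    z_planes: int = 1,
    z_step_nm: float = 125.0,
    seed: int = 0,
    field_size_nm: tuple[float, float] | None = None,
    margin_nm: float = 1500.0,
    depth_of_field_nm: float = 500.0,
) -> dict:
    """Render membrane and DNA image stacks for a set of cells.

    Cells without an explicit center are laid out on a grid. Returns a dict
    with "membrane" and "dna" ImageStacks and a "truth" entry holding each
    cell's contour polygon, medial-axis endpoints, septum and stage.
    Images carry Poisson shot noise on top of a constant background plus
    Gaussian read noise.

    Each plane integrates the 3D model over ``depth_of_field_nm`` around
    its nominal z, which is what makes a closing septum (a transverse
    membrane disc seen through the cell depth) appear bright against the
    interior, as in wide-field images.  Use a small depth of field
    (~150 nm) to emulate optically sectioned (SIM-like) z-stacks.
    """
    specs = list(cell_specs)
    if not specs:
        raise ParameterError("need at least one cell")
    rng = np.random.default_rng(seed)

    # auto-layout on a grid for cells lacking a center
    pitch = max(s.length_nm for s in specs) + 2 * margin_nm
    n_cols = int(math.ceil(math.sqrt(len(specs))))
    for i, s in enumerate(specs):
        if s.center_nm is None:
            row, col = divmod(i, n_cols)
            s.center_nm = (margin_nm + pitch / 2 + col * pitch, margin_nm + pitch / 2 + row * pitch)

    # overlap check on bounding circles
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            ci, cj = np.asarray(specs[i].center_nm), np.asarray(specs[j].center_nm)
            if np.linalg.norm(ci - cj) < (specs[i].length_nm + specs[j].length_nm) / 2:
                raise GenerationError(f"cells {i} and {j} overlap")

    if field_size_nm is None:
        xs = [s.center_nm[0] for s in specs]
        ys = [s.center_nm[1] for s in specs]
        half = max(s.length_nm for s in specs) / 2 + margin_nm
        field_size_nm = (max(xs) + half, max(ys) + half)

    w_px = int(math.ceil(field_size_nm[0] / pixel_size_nm))
    h_px = int(math.ceil(field_size_nm[1] / pixel_size_nm))
    xc = (np.arange(w_px) + 0.5) * pixel_size_nm
    yc = (np.arange(h_px) + 0.5) * pixel_size_nm
    X, Y = np.meshgrid(xc, yc)

    zs = (np.arange(z_planes) - (z_planes - 1) / 2) * z_step_nm
    mem_planes, dna_planes = [], []
    bg = specs[0].background
    noise_sigma = specs[0].noise_sigma
    dz_offsets = (
        np.linspace(-depth_of_field_nm / 2, depth_of_field_nm / 2, 5)
        if depth_of_field_nm > 0
        else np.array([0.0])
    )
    for z in zs:
        mem = np.full((h_px, w_px), float(bg))
        dna = np.full((h_px, w_px), float(bg))
        for s in specs:
            for dz in dz_offsets:
                m, d = _render_cell(s, X, Y, z + dz, psf_sigma_nm)
                mem += m / len(dz_offsets)
                dna += d / len(dz_offsets)
        mem = rng.poisson(np.clip(mem, 0, None)).astype(float)
        dna = rng.poisson(np.clip(dna, 0, None)).astype(float)
        if noise_sigma > 0:
            mem += rng.normal(0, noise_sigma, mem.shape)
            dna += rng.normal(0, noise_sigma, dna.shape)
        mem_planes.append(mem)
        dna_planes.append(dna)

    def _axis_endpoints(s: CellSpec):
        a = math.radians(s.angle_deg)
        d = np.array([math.cos(a), math.sin(a)])
        c = np.asarray(s.center_nm)
        half = s.length_nm / 2 * math.cos(math.radians(s.tilt_deg))
        return (c - half * d, c + half * d)

    truth_cells = []
    for i, s in enumerate(specs):
        p0, p1 = _axis_endpoints(s)
        truth_cells.append(
            {
                "cell_id": i,
                "contour": s.contour(),
                "center_nm": tuple(s.center_nm),
                "axis_endpoints": (tuple(p0), tuple(p1)),
                "length_nm": s.length_nm,
                "width_nm": s.width_nm,
                "septum_rel_pos": s.septum_rel_pos,
                "septum_openness": s.septum_openness,
                "tilt_deg": s.tilt_deg,
                "stage": s.stage,
            }
        )
    kw = dict(pixel_size_nm=pixel_size_nm, z_step_nm=z_step_nm if z_planes > 1 else None)
    return {
        "membrane": ImageStack(np.stack(mem_planes), channel="membrane", **kw),
        "dna": ImageStack(np.stack(dna_planes), channel="dna", **kw),
        "truth": {"cells": truth_cells, "z_positions_nm": zs, "background": bg,
                  "noise_sigma": noise_sigma, "psf_sigma_nm": psf_sigma_nm,
                  "field_size_nm": field_size_nm},
    }


def measure_snr(image: np.ndarray, background: float, noise_sigma: float | None = None) -> float:
    """Peak-signal-to-noise estimate: (99.9th pct − median) / background noise std."""
    corner = image[: max(image.shape[0] // 8, 4), : max(image.shape[1] // 8, 4)]
    noise = corner.std()
    signal = np.percentile(image, 99.9) - np.median(image)
    return float(signal / noise) if noise > 0 else float("inf")


# ---------------------------------------------------------------------------
# full end-to-end scene
# ---------------------------------------------------------------------------

def gen_full_scene(
    seed: int = 0,
    n_cells: int = 3,
    n_frames: int = 3000,
    n_beads: int = 7,
    total_drift_nm: float = 200.0,
    bead_noise_nm: float = 5.0,
    loc_precision_nm: float = 25.0,
    events_per_cluster: int = 200,
) -> dict:
    """A complete acquisition: cells with septum-located emitter clusters,
    drifting fiducials, and raw (drift-contaminated) localizations.

    Cell stages cycle through sporulating / dividing / vegetative. Each
    septum-bearing cell carries one static cluster at its septum midpoint;
    vegetative cells carry one cluster at midcell. The common drift curve
    contaminates both beads and emitter localizations, so the pipeline must
    recover cluster geometry by correcting with the bead-derived model.
    """
    rng = np.random.default_rng(seed)
    stages = [0.2, 0.5, None]  # septum_rel_pos cycle: sporulating, dividing, vegetative
    specs = []
    for i in range(n_cells):
        sp = stages[i % 3]
        specs.append(
            CellSpec(
                length_nm=3000.0 if sp == 0.2 else (4000.0 if sp == 0.5 else 2500.0),
                width_nm=800.0,
                septum_rel_pos=sp,
                septum_openness=0.3 if sp is not None else 0.0,
            )
        )
    scene = gen_cell_scene(specs, seed=int(rng.integers(2**31)))

    field = scene["truth"]["field_size_nm"]
    cluster_specs = []
    for cell in scene["truth"]["cells"]:
        c = np.asarray(cell["center_nm"])
        p0, p1 = (np.asarray(p) for p in cell["axis_endpoints"])
        sp = cell["septum_rel_pos"]
        center = p0 + (sp if sp is not None else 0.5) * (p1 - p0)
        cluster_specs.append(
            {"kind": "static", "center": tuple(center), "sigma_nm": loc_precision_nm,
             "n_events": events_per_cluster}
        )
    cluster_specs.append({"kind": "noise", "n_events": 5, "clearance_nm": 600.0})
    locs, loc_truth = gen_localization_field(
        cluster_specs,
        seed=int(rng.integers(2**31)),
        n_frames=n_frames,
        field_size_nm=field,
        loc_precision_nm=loc_precision_nm,
    )

    beads, bead_truth = gen_bead_tracks(
        n_beads,
        n_frames,
        {"mode": "homogeneous", "total_drift_nm": total_drift_nm},
        noise_nm=bead_noise_nm,
        seed=int(rng.integers(2**31)),
        field_size_nm=field,
    )

    # contaminate emitter localizations with the beads' common drift
    drift = bead_truth["drift"]
    df = locs.df.copy()
    df["x_nm"] = df["x_nm"].to_numpy() + drift[df["frame"].to_numpy(), 0]
    df["y_nm"] = df["y_nm"].to_numpy() + drift[df["frame"].to_numpy(), 1]
    raw_locs = locs.with_df(df)

    return {
        "cells": scene,
        "locs_raw": raw_locs,
        "locs_clean": locs,
        "loc_truth": loc_truth,
        "beads": beads,
        "bead_truth": bead_truth,
        "n_frames": n_frames,
    }
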