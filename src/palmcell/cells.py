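"""Cell detection, contour refinement, septum detection and cell-cycle
sorting.

Nucleoid (DNA-stain) images seed the segmentation: chromosomes are confined
inside cells, so nucleoid signals stay separated even when neighbouring
cells touch.  Because the nucleoid underfills the cell, the seed contour is
then refined against the membrane-stain image by moving each vertex along
its outward normal to the local intensity maximum.  The membrane intensity
profile along the medial axis reveals the septum: no septum means a
vegetative/pre-divisional cell; a septum in the middle third of the cell
length marks a dividing cell; a septum in either outer third marks a
sporulating cell (asymmetric septation).  Finally, localization clusters
are assigned to the cell whose (slightly dilated) contour contains their
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from shapely.geometry import Point, Polygon
from skimage import draw, filters, measure, morphology, segmentation

from .clustering import ClusterRecord
from .errors import AmbiguityError, ParameterError
from .io_core import ImageStack


@dataclass
class IntensityProfile:
    """Intensity sampled along a cell's medial axis (arc length in nm)."""

    positions_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions_nm) != len(self.intensities):
            raise ParameterError("positions and intensities must be equally long")
        if len(self.positions_nm) > 1 and not (np.diff(self.positions_nm) > 0).all():
            raise ParameterError("positions must be strictly increasing")

    @property
    def length_nm(self) -> float:
        return float(self.positions_nm[-1] - self.positions_nm[0]) if len(self.positions_nm) else 0.0


@dataclass
class CellRecord:
    """One detected cell: geometry, cell-cycle stage, assigned clusters."""

    cell_id: int
    contour_nm: np.ndarray  # closed polygon (n, 2)
    medial_axis_nm: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    length_nm: float = 0.0
    septum_rel_pos: float | None = None
    stage: str | None = None
    cluster_ids: list[int] = field(default_factory=list)
    low_confidence: bool = False
    needs_review: bool = True  # manual-verification hook; cleared by a reviewer

    @property
    def centroid_nm(self) -> np.ndarray:
        poly = Polygon(self.contour_nm)
        return np.asarray(poly.centroid.coords[0])


# ---------------------------------------------------------------------------
# nucleoid seeding
# ---------------------------------------------------------------------------

def segment_nucleoids(
    dna_plane: np.ndarray,
    pixel_size_nm: float,
    min_area_px: int = 9,
) -> list[dict]:
    """Seed contours from a DNA image: Otsu threshold, morphological
    opening, connected components; border-touching objects are discarded.

    Returns one dict per seed with ``contour_nm`` (closed polygon) and
    ``centroid_nm``.
    """
    img = np.asarray(dna_plane, dtype=float)
    if img.size == 0 or img.std() < 1e-12:
        return []
    thresh = filters.threshold_otsu(img)
    mask = img > thresh
    mask = morphology.opening(mask, morphology.disk(1))
    mask = segmentation.clear_border(mask)
    labeled, n = ndimage.label(mask)
    seeds = []
    for lab in range(1, n + 1):
        obj = labeled == lab
        if obj.sum() < min_area_px:
            continue
        contours = measure.find_contours(obj.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # (row, col) in pixel units
        poly_nm = np.column_stack([(contour[:, 1] + 0.5), (contour[:, 0] + 0.5)]) * pixel_size_nm
        cy, cx = ndimage.center_of_mass(obj)
        seeds.append(
            {
                "contour_nm": poly_nm,
                "centroid_nm": np.array([(cx + 0.5) * pixel_size_nm, (cy + 0.5) * pixel_size_nm]),
            }
        )
    seeds.sort(key=lambda s: (s["centroid_nm"][1], s["centroid_nm"][0]))
    return seeds


# ---------------------------------------------------------------------------
# contour refinement against the membrane image
# ---------------------------------------------------------------------------

def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points equally spaced in arc length."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0, total, n, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def _sample_image(img: np.ndarray, pts_nm: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Bilinear intensity at nm positions (pixel centers at (i+0.5)*ps)."""
    cols = pts_nm[:, 0] / pixel_size_nm - 0.5
    rows = pts_nm[:, 1] / pixel_size_nm - 0.5
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _smooth_closed(poly: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return poly
    kernel = np.ones(window) / window
    out = np.empty_like(poly)
    for ax in range(2):
        padded = np.concatenate([poly[-window:, ax], poly[:, ax], poly[:window, ax]])
        out[:, ax] = np.convolve(padded, kernel, mode="same")[window:-window]
    return out


def refine_contour(
    seed_nm: np.ndarray,
    membrane_plane: np.ndarray,
    pixel_size_nm: float,
    search_range_nm: float = 1200.0,
    max_iter: int = 20,
    tol_nm: float = 5.0,
    n_vertices: int = 140,
    smooth_window: int = 5,
) -> tuple[np.ndarray, bool]:
    """Snap a seed contour onto the membrane intensity ridge.

    Each vertex moves along its outward local normal to the intensity
    maximum within ``search_range_nm``; the polygon is then smoothed by a
    circular moving average.  Iterates until the mean vertex displacement
    drops below ``tol_nm`` or ``max_iter``.  Returns (refined_polygon,
    low_confidence): the flag is set when >= 30% of the normals find no
    membrane signal above background.
    """
    img = np.asarray(membrane_plane, dtype=float)
    bg = float(np.median(img))
    mad = float(np.median(np.abs(img - bg))) * 1.4826
    poly = _resample_closed(np.asarray(seed_nm, dtype=float), n_vertices)
    # seeds underfill the cell (the nucleoid sits inside the membrane), so
    # the search is mostly outward; a short inward slack absorbs seed noise
    # without letting vertices collapse onto bright interior structure
    # (e.g. a septum ring)
    inward_nm = search_range_nm / 8
    n_off = max(int((search_range_nm + inward_nm) / (pixel_size_nm / 4)) | 1, 41)
    offsets = np.linspace(-inward_nm, search_range_nm, n_off)
    low_conf = False
    for _ in range(max_iter):
        centroid = poly.mean(axis=0)
        nxt = np.roll(poly, -1, axis=0)
        prv = np.roll(poly, 1, axis=0)
        tangent = nxt - prv
        normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
        norms = np.linalg.norm(normal, axis=1, keepdims=True)
        normal = normal / np.where(norms > 0, norms, 1.0)
        outward = np.sign(np.sum(normal * (poly - centroid), axis=1))
        normal *= np.where(outward == 0, 1.0, outward)[:, None]

        sample_pts = poly[:, None, :] + normal[:, None, :] * offsets[None, :, None]
        flat = sample_pts.reshape(-1, 2)
        vals = _sample_image(img, flat, pixel_size_nm).reshape(len(poly), len(offsets))
        # distance-penalized maximum: between near-equal ridges (e.g. the
        # opposite membrane wall within reach) the nearest one wins
        span = vals.max(axis=1, keepdims=True) - vals.min(axis=1, keepdims=True)
        penalty = 0.25 * span * (np.abs(offsets) / search_range_nm)[None, :]
        best = (vals - penalty).argmax(axis=1)
        peak_vals = vals[np.arange(len(poly)), best]
        no_signal = peak_vals <= bg + 3.0 * mad + 1e-6 * max(abs(bg), 1.0)
        low_conf = bool(no_signal.mean() >= 0.30)
        new_poly = poly + normal * offsets[best][:, None]
        new_poly = _smooth_closed(new_poly, smooth_window)
        displacement = float(np.linalg.norm(new_poly - poly, axis=1).mean())
        poly = new_poly
        if displacement < tol_nm:
            break
    return poly, low_conf


# ---------------------------------------------------------------------------
# medial axis and membrane profile
# ---------------------------------------------------------------------------

def medial_axis_from_contour(
    contour_nm: np.ndarray, pixel_size_nm: float
) -> tuple[np.ndarray, float]:
    """Medial axis polyline of a rod-shaped contour, extended to the poles.

    The contour is rasterized, skeletonized, and the skeleton pixels are
    ordered along the principal axis; the two ends are then extended to the
    contour boundary along the local axis direction.  Returns (polyline_nm,
    length_nm).
    """
    contour_nm = np.asarray(contour_nm, dtype=float)
    poly = Polygon(contour_nm)
    # rasterize at a finer grid for a smooth skeleton
    step = pixel_size_nm / 2
    minx, miny, maxx, maxy = poly.bounds
    w = int(np.ceil((maxx - minx) / step)) + 3
    h = int(np.ceil((maxy - miny) / step)) + 3
    rr, cc = draw.polygon(
        (contour_nm[:, 1] - miny) / step + 1, (contour_nm[:, 0] - minx) / step + 1, shape=(h, w)
    )
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    skel = morphology.skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if len(xs) < 2:
        c = np.asarray(poly.centroid.coords[0])
        return np.array([c, c]), 0.0
    pts = np.column_stack([xs * step + minx - step, ys * step + miny - step])
    # order along the principal axis
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis_dir = vt[0]
    order = np.argsort(centered @ axis_dir, kind="stable")
    path = pts[order]
    # smooth the ordered skeleton
    if len(path) >= 7:
        kernel = np.ones(7) / 7
        path = np.column_stack(
            [np.convolve(path[:, i], kernel, mode="valid") for i in range(2)]
        )
    # extend ends to the contour along local directions
    boundary = poly.exterior

    def _extend(end: np.ndarray, direction: np.ndarray) -> np.ndarray:
        d = direction / (np.linalg.norm(direction) or 1.0)
        lengths = np.linspace(0, 3 * pixel_size_nm * 20, 200)
        candidates = end[None, :] + lengths[:, None] * d[None, :]
        inside = np.array([poly.contains(Point(p)) for p in candidates])
        if inside.all():
            return candidates[-1]
        first_out = int(np.argmin(inside))
        return candidates[max(first_out - 1, 0)]

    # extend along the global principal axis: robust to skeleton end spurs
    head = _extend(path[0], -axis_dir if (path[-1] - path[0]) @ axis_dir > 0 else axis_dir)
    tail = _extend(path[-1], axis_dir if (path[-1] - path[0]) @ axis_dir > 0 else -axis_dir)
    full = np.vstack([head, path, tail])
    length = float(np.sum(np.linalg.norm(np.diff(full, axis=0), axis=1)))
    return full, length


def membrane_profile(
    cell: CellRecord,
    membrane_plane: np.ndarray,
    pixel_size_nm: float,
    n_width_samples: int = 7,
) -> IntensityProfile:
    """Membrane intensity along the medial axis, averaged across the local
    cell width, sampled at half-pixel spacing."""
    axis = cell.medial_axis_nm
    if len(axis) < 2 or cell.length_nm <= 0:
        raise ParameterError("cell has a degenerate medial axis")
    img = np.asarray(membrane_plane, dtype=float)
    poly = Polygon(cell.contour_nm)
    boundary = poly.exterior

    # resample the axis at <= pixel/2 spacing
    seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_samples = max(int(np.ceil(cum[-1] / (pixel_size_nm / 2))), 2)
    s = np.linspace(0, cum[-1], n_samples)
    ax = np.column_stack([np.interp(s, cum, axis[:, 0]), np.interp(s, cum, axis[:, 1])])

    tangents = np.gradient(ax, axis=0)
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)

    halfwidth = np.array([boundary.distance(Point(p)) for p in ax])
    offsets = np.linspace(-1.0, 1.0, n_width_samples)
    vals = np.empty((n_samples, n_width_samples))
    for j, f in enumerate(offsets):
        pts = ax + normals * (halfwidth * f)[:, None]
        vals[:, j] = _sample_image(img, pts, pixel_size_nm)
    return IntensityProfile(positions_nm=s, intensities=vals.mean(axis=1))


# ---------------------------------------------------------------------------
# septum detection and staging
# ---------------------------------------------------------------------------

def detect_septum(
    profile: IntensityProfile,
    pole_margin: float = 0.15,
    prominence_factor: float = 1.5,
    min_contrast: float = 0.4,
) -> float | None:
    """Relative position of the septum along the cell, or None.

    The candidate is the highest interior intensity peak whose relative
    position lies in [pole_margin, 1 - pole_margin] and whose prominence is
    at least ``prominence_factor`` times the median intensity *above the
    interior baseline* (the profile's 10th percentile); pole peaks
    (membrane caps) are excluded by the margin.  Measuring against the
    baseline-subtracted profile keeps the criterion meaningful when the
    interior carries diffuse membrane signal.
    """
    y = profile.intensities
    if len(y) < 5 or profile.length_nm <= 0:
        return None
    baseline = float(np.percentile(y, 10))
    median = float(np.median(y - baseline))
    # a genuine septum is a major feature: besides the median-relative
    # prominence it must reach min_contrast of the profile's full contrast,
    # which rejects interior noise bumps on flat vegetative profiles
    floor = max(prominence_factor * median, min_contrast * (float(y.max()) - baseline), 1e-12)
    peaks, props = find_peaks(y, prominence=floor)
    if len(peaks) == 0:
        return None
    rel = (profile.positions_nm[peaks] - profile.positions_nm[0]) / profile.length_nm
    interior = (rel >= pole_margin) & (rel <= 1 - pole_margin)
    if not interior.any():
        return None
    cand_peaks = peaks[interior]
    best = int(cand_peaks[np.argmax(y[cand_peaks])])
    pos = profile.positions_nm[best]
    # parabolic sub-sample refinement of the peak position
    if 0 < best < len(y) - 1:
        denom = y[best - 1] - 2 * y[best] + y[best + 1]
        if denom < 0:
            shift = 0.5 * (y[best - 1] - y[best + 1]) / denom
            step = profile.positions_nm[best + 1] - profile.positions_nm[best]
            pos = pos + np.clip(shift, -1, 1) * step
    return float((pos - profile.positions_nm[0]) / profile.length_nm)


def classify_stage(septum_rel_pos: float | None) -> str:
    """Three-compartment cell-cycle sorting.

    No septum: vegetative/pre-divisional.  Septum in the middle third of
    the cell: dividing.  Septum in an outer third: sporulating (asymmetric
    septation).  Boundary positions at exactly 1/3 or 2/3 classify as
    dividing (the more conservative class).
    """
    if septum_rel_pos is None:
        return "vegetative_predivisional"
    if 1 / 3 <= septum_rel_pos <= 2 / 3:
        return "dividing"
    return "sporulating"


# ---------------------------------------------------------------------------
# cluster-to-cell assignment
# ---------------------------------------------------------------------------

def assign_clusters_to_cells(
    cells: list[CellRecord],
    clusters: list[ClusterRecord],
    loc_precision_nm: float = 25.0,
) -> list[int]:
    """Assign each cluster to the unique cell containing its centroid.

    Contours are dilated by one localization precision so membrane-bound
    clusters sitting just outside the refined contour still assign.
    Returns the list of orphan cluster ids.  A centroid inside two
    *undilated* contours raises AmbiguityError (overlapping contours).
    """
    polys = [Polygon(c.contour_nm) for c in cells]
    dilated = [p.buffer(loc_precision_nm) for p in polys]
    for c in cells:
        c.cluster_ids = []
    orphans = []
    for cl in clusters:
        pt = Point(cl.centroid_nm)
        strict = [i for i, p in enumerate(polys) if p.contains(pt)]
        if len(strict) > 1:
            raise AmbiguityError(
                f"cluster {cl.cluster_id} centroid lies inside {len(strict)} cell contours"
            )
        if strict:
            cells[strict[0]].cluster_ids.append(cl.cluster_id)
            continue
        loose = [i for i, p in enumerate(dilated) if p.contains(pt)]
        if len(loose) == 1:
            cells[loose[0]].cluster_ids.append(cl.cluster_id)
        elif len(loose) > 1:
            # between two dilated contours: nearest undilated contour wins
            d = [polys[i].exterior.distance(pt) for i in loose]
            cells[loose[int(np.argmin(d))]].cluster_ids.append(cl.cluster_id)
        else:
            orphans.append(cl.cluster_id)
    return orphans


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def detect_cells(
    dna: ImageStack,
    membrane: ImageStack,
    plane: int = 0,
    refine_kwargs: dict | None = None,
) -> list[CellRecord]:
    """DNA-seeded detection, membrane refinement, septum detection, staging."""
    ps = membrane.pixel_size_nm
    seeds = segment_nucleoids(dna.planes[plane], dna.pixel_size_nm)
    records = []
    for i, seed in enumerate(seeds):
        refined, low_conf = refine_contour(
            seed["contour_nm"], membrane.planes[plane], ps, **(refine_kwargs or {})
        )
        cell = CellRecord(cell_id=i, contour_nm=refined, low_confidence=low_conf)
        cell.medial_axis_nm, cell.length_nm = medial_axis_from_contour(refined, ps)
        if cell.length_nm > 0:
            profile = membrane_profile(cell, membrane.planes[plane], ps)
            cell.septum_rel_pos = detect_septum(profile)
        cell.stage = classify_stage(cell.septum_rel_pos)
        records.append(cell)
    return records


def cells_to_json(cells: list[CellRecord], path) -> None:
    """Geometry-complete cell records (contours, medial axes) as JSON."""
    import json
    from pathlib import Path

    payload = [
        {
            "cell_id": c.cell_id,
            "contour_nm": c.contour_nm.tolist(),
            "medial_axis_nm": c.medial_axis_nm.tolist(),
            "length_nm": c.length_nm,
            "septum_rel_pos": c.septum_rel_pos,
            "stage": c.stage,
            "cluster_ids": c.cluster_ids,
            "low_confidence": c.low_confidence,
            "needs_review": c.needs_review,
        }
        for c in cells
    ]
    Path(path).write_text(json.dumps(payload))


def cells_from_json(path) -> list[CellRecord]:
    import json
    from pathlib import Path

    out = []
    for d in json.loads(Path(path).read_text()):
        out.append(
            CellRecord(
                cell_id=d["cell_id"],
                contour_nm=np.asarray(d["contour_nm"]),
                medial_axis_nm=np.asarray(d["medial_axis_nm"]),
                length_nm=d["length_nm"],
                septum_rel_pos=d["septum_rel_pos"],
                stage=d["stage"],
                cluster_ids=list(d["cluster_ids"]),
                low_confidence=d["low_confidence"],
                needs_review=d["needs_review"],
            )
        )
    return out


def cells_to_frame(cells: list[CellRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "length_nm": c.length_nm,
                "septum_rel_pos": c.septum_rel_pos,
                "stage": c.stage,
                "n_clusters": len(c.cluster_ids),
                "low_confidence": c.low_confidence,
                "needs_review": c.needs_review,
            }
            for c in cells
        ]
    )
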