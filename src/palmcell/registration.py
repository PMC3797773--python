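"""Channel registration by a second-order polynomial transform.

Sequential multi-color acquisitions taken through different filters are
misaligned by translation, rotation, magnification changes and chromatic
aberration.  A per-axis polynomial on the basis {1, x, y, x², xy, y²} is
fitted by least squares to matched fiducial positions in the two channels
(default minimum of 7 beads; 6 suffice algebraically, the 7th adds
redundancy) and then applied to all localizations of the source channel.
Coordinates are centered and scaled internally for conditioning; results
are returned in nm, with residuals reported both in nm and in camera
pixels since the accepted quality bound is conventionally quoted as
0.1 pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegeneracyError, InsufficientBeadsError, ParameterError

DEFAULT_MIN_BEADS = 7


def _design(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass
class ChannelTransform:
    """Fitted per-axis second-order polynomial (basis 1, x, y, x², xy, y²).

    Coefficients are stored for *normalized* coordinates together with the
    normalization (center, scale); ``coeffs_nm`` recovers the nm-basis
    coefficients for inspection.
    """

    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    center: np.ndarray
    scale: float
    residual_rms_nm: float = 0.0
    residual_max_nm: float = 0.0
    pixel_size_nm: float = 110.0
    beads_used: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)
        if self.coeffs_x.shape != (6,) or self.coeffs_y.shape != (6,):
            raise ParameterError("exactly 6 coefficients per axis required")
        if self.residual_rms_nm < 0 or self.residual_max_nm < 0:
            raise ParameterError("residuals must be >= 0")

    @property
    def residual_rms_px(self) -> float:
        return self.residual_rms_nm / self.pixel_size_nm

    @property
    def residual_max_px(self) -> float:
        return self.residual_max_nm / self.pixel_size_nm

    def coeffs_nm(self) -> dict:
        """Coefficients re-expressed on the raw nm basis."""
        cx, cy = self.center
        s = self.scale

        def _expand(c):
            # substitute u=(x-cx)/s, v=(y-cy)/s into c0+c1 u+c2 v+c3 u²+c4 uv+c5 v²
            c0, c1, c2, c3, c4, c5 = c
            a_const = c0 - c1 * cx / s - c2 * cy / s + c3 * cx**2 / s**2 + c4 * cx * cy / s**2 + c5 * cy**2 / s**2
            a_x = c1 / s - 2 * c3 * cx / s**2 - c4 * cy / s**2
            a_y = c2 / s - c4 * cx / s**2 - 2 * c5 * cy / s**2
            return [a_const, a_x, a_y, c3 / s**2, c4 / s**2, c5 / s**2]

        return {"x": _expand(self.coeffs_x), "y": _expand(self.coeffs_y)}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "coeffs_x": self.coeffs_x.tolist(),
                    "coeffs_y": self.coeffs_y.tolist(),
                    "center": self.center.tolist(),
                    "scale": self.scale,
                    "residual_rms_nm": self.residual_rms_nm,
                    "residual_max_nm": self.residual_max_nm,
                    "pixel_size_nm": self.pixel_size_nm,
                    "beads_used": self.beads_used,
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            coeffs_x=np.asarray(d["coeffs_x"]),
            coeffs_y=np.asarray(d["coeffs_y"]),
            center=np.asarray(d["center"]),
            scale=d["scale"],
            residual_rms_nm=d["residual_rms_nm"],
            residual_max_nm=d["residual_max_nm"],
            pixel_size_nm=d["pixel_size_nm"],
            beads_used=list(d["beads_used"]),
        )


def select_beads_g_optimal(
    positions: np.ndarray,
    k: int = DEFAULT_MIN_BEADS,
    eval_positions: np.ndarray | None = None,
    max_subsets: int = 5000,
) -> np.ndarray:
    """Automatically select k fitting beads by G-optimal design.

    Chooses the subset whose second-order design minimizes the maximum
    prediction variance over the evaluation positions (default: all
    beads).  Uses bead *positions* only — no intensity or residual
    information — so the selection cannot bias the fit.  Falls back to a
    farthest-point greedy when the exhaustive search would exceed
    ``max_subsets`` combinations.
    """
    from itertools import combinations
    from math import comb

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if k >= n:
        return np.arange(n)
    if eval_positions is None:
        eval_positions = positions
    center = positions.mean(axis=0)
    scale = float(np.std(positions)) or 1.0
    A_eval = _design((np.asarray(eval_positions) - center) / scale)
    A_all = _design((positions - center) / scale)

    def _max_pred_var(idx):
        As = A_all[list(idx)]
        M = As.T @ As
        if np.linalg.matrix_rank(M) < 6:
            return np.inf
        Minv = np.linalg.inv(M)
        return float(np.einsum("ij,jk,ik->i", A_eval, Minv, A_eval).max())

    if comb(n, k) <= max_subsets:
        best = min(combinations(range(n), k), key=_max_pred_var)
        return np.asarray(best, dtype=int)
    # greedy farthest-point fallback for large fields
    idx = [int(np.argmin(np.linalg.norm(positions - center, axis=1)))]
    while len(idx) < k:
        d = np.min(
            np.linalg.norm(positions[:, None, :] - positions[idx][None, :, :], axis=2), axis=1
        )
        d[idx] = -1.0
        idx.append(int(np.argmax(d)))
    return np.asarray(sorted(idx), dtype=int)


def fit_channel_transform(
    src: np.ndarray,
    dst: np.ndarray,
    min_beads: int = DEFAULT_MIN_BEADS,
    pixel_size_nm: float = 110.0,
    bead_ids: list[int] | None = None,
) -> ChannelTransform:
    """Least-squares fit of the per-axis 6-term polynomial mapping src → dst.

    ``src`` and ``dst`` are matched (n, 2) bead positions in nm.  Raises
    InsufficientBeadsError below ``min_beads`` pairs and DegeneracyError for
    a rank-deficient design (e.g. collinear beads).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ParameterError("src and dst must be matched (n, 2) arrays")
    n = len(src)
    if n < min_beads:
        raise InsufficientBeadsError(f"{n} matched beads < required minimum {min_beads}")

    center = src.mean(axis=0)
    scale = float(np.std(src)) or 1.0
    u = (src - center) / scale
    A = _design(u)
    if np.linalg.matrix_rank(A) < 6:
        raise DegeneracyError("bead configuration is degenerate (collinear or coincident)")
    cx, *_ = np.linalg.lstsq(A, dst[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, dst[:, 1], rcond=None)

    fitted = np.column_stack([A @ cx, A @ cy])
    res = fitted - dst
    per_axis_max = float(np.abs(res).max())
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return ChannelTransform(
        coeffs_x=cx,
        coeffs_y=cy,
        center=center,
        scale=scale,
        residual_rms_nm=rms,
        residual_max_nm=per_axis_max,
        pixel_size_nm=pixel_size_nm,
        beads_used=list(bead_ids) if bead_ids is not None else list(range(n)),
    )


def transform_points(transform: ChannelTransform, points: np.ndarray) -> np.ndarray:
    """Apply the fitted polynomial to (n, 2) points in nm."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    u = (points - transform.center) / transform.scale
    A = _design(u)
    return np.column_stack([A @ transform.coeffs_x, A @ transform.coeffs_y])
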