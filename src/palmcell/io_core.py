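"""Core data model and I/O for localization tables and image stacks.

Conventions
-----------
Positions are continuous, in nanometres, with the origin at the top-left
corner of the field; the pixel index of a position is ``floor(pos /
pixel_size_nm)``.  Frames are 0-based and the time of an event is ``frame *
frame_time_ms``.  Localization CSVs are comma-separated, dot-decimal, UTF-8,
with header ``frame,x_nm,y_nm,intensity,channel,id``; a column map allows
ingesting foreign headers (e.g. ThunderSTORM's ``x [nm]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError, ParseError, SchemaError

#: canonical column order of the on-disk CSV
CSV_COLUMNS = ("frame", "x_nm", "y_nm", "intensity", "channel", "id")

_NUMERIC = ("frame", "x_nm", "y_nm", "intensity", "id")


@dataclass(frozen=True)
class Localization:
    """A single blinking event: one emitter localized in one frame."""

    frame: int
    x_nm: float
    y_nm: float
    intensity: float = 0.0
    channel: str = "default"
    id: int = 0


@dataclass
class LocalizationTable:
    """Ordered collection of localizations plus acquisition metadata.

    The pipeline's currency: every stage consumes and emits this type.
    Backed by a pandas DataFrame with the canonical columns, sorted by
    (frame, id).
    """

    df: pd.DataFrame
    pixel_size_nm: float = 110.0
    frame_time_ms: float = 50.0
    loc_precision_nm: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size_nm <= 0 or self.frame_time_ms <= 0 or self.loc_precision_nm <= 0:
            raise ParameterError("pixel_size_nm, frame_time_ms, loc_precision_nm must be > 0")
        df = self.df
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = df.loc[:, list(CSV_COLUMNS)].copy()
        df["frame"] = df["frame"].astype(np.int64)
        df["id"] = df["id"].astype(np.int64)
        for c in ("x_nm", "y_nm", "intensity"):
            df[c] = df[c].astype(float)
        df["channel"] = df["channel"].astype(str)
        df = df.sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)
        if len(df):
            if (df["frame"] < 0).any():
                raise ParameterError("frames must be >= 0")
            if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy()).all():
                raise ParameterError("x/y must be finite")
            if (df["intensity"] < 0).any():
                raise ParameterError("intensity must be >= 0")
            if df["id"].duplicated().any():
                raise ParameterError("localization ids must be unique")
        self.df = df

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy()

    @property
    def frames(self) -> np.ndarray:
        return self.df["frame"].to_numpy()

    def times_ms(self) -> np.ndarray:
        return self.frames * self.frame_time_ms

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return replace(self, df=df)

    @classmethod
    def from_arrays(
        cls,
        frame: Sequence[int],
        x_nm: Sequence[float],
        y_nm: Sequence[float],
        intensity: Sequence[float] | None = None,
        channel: str | Sequence[str] = "default",
        ids: Sequence[int] | None = None,
        **meta_kwargs,
    ) -> "LocalizationTable":
        n = len(x_nm)
        df = pd.DataFrame(
            {
                "frame": np.asarray(frame, dtype=np.int64),
                "x_nm": np.asarray(x_nm, dtype=float),
                "y_nm": np.asarray(y_nm, dtype=float),
                "intensity": np.zeros(n) if intensity is None else np.asarray(intensity, float),
                "channel": channel if not isinstance(channel, str) else [channel] * n,
                "id": np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, np.int64),
            }
        )
        return cls(df, **meta_kwargs)

    @classmethod
    def empty(cls, **meta_kwargs) -> "LocalizationTable":
        return cls.from_arrays([], [], [], **meta_kwargs)


@dataclass
class ImageStack:
    """A stack of same-shaped 2D intensity planes, indexed by z or time."""

    planes: np.ndarray  # (n, h, w)
    pixel_size_nm: float = 110.0
    z_step_nm: float | None = None
    channel: str = "default"

    def __post_init__(self):
        planes = np.asarray(self.planes, dtype=float)
        if planes.ndim == 2:
            planes = planes[None]
        if planes.ndim != 3:
            raise ParameterError("planes must be a 2D image or a stack of 2D images")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be > 0")
        self.planes = planes

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


# -- localization table I/O ----------------------------------------------------

#: ready-made column map for ThunderSTORM export headers
THUNDERSTORM_DIALECT = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "intensity [photon]": "intensity",
}


def read_localization_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    **meta_kwargs,
) -> LocalizationTable:
    """Read a localization CSV.

    Parameters
    ----------
    path
        CSV file with a header line.
    dialect
        Optional map from file column names to canonical names
        (``frame, x_nm, y_nm, intensity, channel, id``), for ingesting
        foreign exports.

    Raises
    ------
    SchemaError
        If a required column is absent (names the column).
    ParseError
        If a data cell is non-numeric (cites the 1-based file line).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    if dialect:
        raw = raw.rename(columns=dict(dialect))
    for col in ("frame", "x_nm", "y_nm"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column '{col}' in {path.name}")
    if "intensity" not in raw.columns:
        raw["intensity"] = "0"
    if "channel" not in raw.columns:
        raw["channel"] = "default"
    if "id" not in raw.columns:
        raw["id"] = np.arange(len(raw)).astype(str)
    for col in _NUMERIC:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"non-numeric value {raw[col][row]!r} in column '{col}'", line=row + 2
            )
        raw[col] = coerced
    raw = raw.dropna(subset=["frame", "x_nm", "y_nm"])
    return LocalizationTable(raw, **meta_kwargs)


def write_localization_table(table: LocalizationTable, path: str | Path) -> Path:
    """Write the canonical CSV; numeric columns keep full precision."""
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.6f")
    return path


# -- image stack I/O -----------------------------------------------------------

def read_image_stack(
    path: str | Path,
    pixel_size_nm: float = 110.0,
    z_step_nm: float | None = None,
    channel: str = "default",
) -> ImageStack:
    """Read a single- or multi-page TIFF as an ImageStack.

    Metadata that TIFF does not carry (pixel size, z-step) is supplied by
    the caller, typically from the pipeline config.
    """
    path = Path(path)
    try:
        planes = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types for bad magic
        raise FormatError(f"{path.name} is not a readable TIFF: {exc}") from exc
    return ImageStack(planes, pixel_size_nm=pixel_size_nm, z_step_nm=z_step_nm, channel=channel)


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.planes.astype(np.float32))
    return path
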