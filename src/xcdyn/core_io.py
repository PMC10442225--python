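"""Shared data containers and file I/O for the pipeline.

Every downstream module consumes the validated containers defined here;
no analysis operation reads files directly.

Conventions
-----------
* Lengths in micrometres (μm), times in seconds, concentrations in nM.
* Frames are 0-based integers.
* Localization → pixel mapping: ``column = floor(x / pixel_size)``,
  ``row = floor(y / pixel_size)``, origin at the top-left pixel corner.
* Trajectory CSV columns: ``trajectory_id, frame, x_um, y_um``.
* Region masks are single-channel TIFFs, nonzero = inside the region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

DEFAULT_PIXEL_SIZE = 0.106
"""Camera pixel size in μm (Nyquist sampling of the SPT setup)."""

DEFAULT_FRAME_INTERVAL = 0.005477
"""SPT frame interval in seconds."""

DEFAULT_BLEACH_FRAME = 80
"""Default frame index of the FRAP photobleach pulse."""

REGION_NAMES = ("nucleus", "xc", "nucleoli", "nucleoplasm")


class FormatError(ValueError):
    """A file does not have the expected columns/layout."""


class ValidationError(ValueError):
    """Data violate a container invariant."""


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ("trajectory_id", "frame", "x", "y")


@dataclass
class TrajectoryTable:
    """Localizations grouped into trajectories.

    Parameters
    ----------
    records
        DataFrame with columns ``trajectory_id`` (int), ``frame``
        (int, 0-based), ``x``, ``y`` (μm). Sorted by (trajectory_id, frame)
        on construction.
    frame_interval
        Time between consecutive frames, in seconds.
    pixel_size
        Size of a camera pixel in μm (used for mask co-registration).
    source_id
        Free-text identifier of the originating cell/movie.
    """

    records: pd.DataFrame
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE
    source_id: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trajectory table missing columns: {missing}")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        df = df.sort_values(["trajectory_id", "frame"], kind="stable")
        df = df.reset_index(drop=True)
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValidationError("coordinates must be finite")
        if (df[["x", "y"]].to_numpy() < 0).any():
            raise ValidationError("coordinates must be non-negative")
        if (df["frame"].to_numpy() < 0).any():
            raise ValidationError("frames must be >= 0")
        # frames must strictly increase within each trajectory
        same = df["trajectory_id"].to_numpy()[1:] == df["trajectory_id"].to_numpy()[:-1]
        nondec = np.diff(df["frame"].to_numpy()) <= 0
        bad = same & nondec
        if bad.any():
            tid = df["trajectory_id"].to_numpy()[1:][bad][0]
            raise ValidationError(
                f"frames do not strictly increase within trajectory {tid}"
            )
        object.__setattr__(self, "records", df)

    @property
    def n_trajectories(self) -> int:
        return int(self.records["trajectory_id"].nunique())

    @property
    def n_localizations(self) -> int:
        return int(len(self.records))

    def to_csv(self, path: str | Path) -> None:
        out = self.records.rename(columns={"x": "x_um", "y": "y_um"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_interval: float = DEFAULT_FRAME_INTERVAL,
        pixel_size: float = DEFAULT_PIXEL_SIZE,
        source_id: str = "",
    ) -> "TrajectoryTable":
        df = pd.read_csv(path)
        df = df.rename(columns={"x_um": "x", "y_um": "y"})
        missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        return cls(
            records=df[list(_TRAJ_COLUMNS)],
            frame_interval=frame_interval,
            pixel_size=pixel_size,
            source_id=source_id or str(path),
        )


def load_trajectories(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> TrajectoryTable:
    """Read a trajectory CSV (``trajectory_id, frame, x_um, y_um``)."""
    return TrajectoryTable.from_csv(path, frame_interval=frame_interval, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Region masks
# ---------------------------------------------------------------------------


@dataclass
class RegionMaskSet:
    """Co-registered boolean rasters for the nuclear sub-regions.

    ``xc`` is the RNA-coated compartment; ``nucleoli`` and ``nucleoplasm``
    are control regions. All rasters share one pixel grid. For 3D stacks
    the leading axis is z and ``voxel_depth`` gives the z spacing in μm.
    """

    nucleus: np.ndarray
    xc: np.ndarray
    nucleoli: np.ndarray
    nucleoplasm: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    voxel_depth: float | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        for name in REGION_NAMES:
            arr = np.asarray(getattr(self, name)).astype(bool)
            object.__setattr__(self, name, arr)
        shapes = {getattr(self, n).shape for n in REGION_NAMES}
        if len(shapes) != 1:
            raise ValidationError(f"mask shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        empties = [n for n in REGION_NAMES if not getattr(self, n).any()]
        object.__setattr__(self, "empty_regions", tuple(empties))
        if "nucleus" in empties:
            warnings.warn("nucleus mask is empty", stacklevel=2)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.nucleus.shape

    def region(self, name: str) -> np.ndarray:
        if name not in REGION_NAMES:
            raise KeyError(f"unknown region {name!r}")
        return getattr(self, name)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in REGION_NAMES:
            tifffile.imwrite(
                directory / f"{name}.tif", getattr(self, name).astype(np.uint8)
            )


def load_mask_set(
    paths: Mapping[str, str | Path],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    voxel_depth: float | None = None,
    tag: str = "",
) -> RegionMaskSet:
    """Read a set of region TIFFs (nonzero = inside) into a mask set.

    ``paths`` maps region names (``nucleus``, ``xc``, ``nucleoli``,
    ``nucleoplasm``) to TIFF files of identical shape.
    """
    masks = {}
    for name in REGION_NAMES:
        if name not in paths:
            raise FormatError(f"missing mask path for region {name!r}")
        masks[name] = np.asarray(tifffile.imread(paths[name])) != 0
    return RegionMaskSet(pixel_size=pixel_size, voxel_depth=voxel_depth, tag=tag, **masks)


# ---------------------------------------------------------------------------
# FCS curves
# ---------------------------------------------------------------------------


@dataclass
class FcsCurve:
    """A fluorescence-correlation autocorrelation curve G(τ).

    ``label`` distinguishes pure-dye, freely-diffusing-control, protein and
    negative-control measurements; dye curves are fitted on a restricted
    lag range downstream.
    """

    lag: np.ndarray
    G: np.ndarray
    paired_intensity: float | None = None
    label: str = "protein"

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if lag.shape != G.shape or lag.ndim != 1:
            raise ValidationError("lag and G must be 1D arrays of equal length")
        if not (np.diff(lag) > 0).all():
            raise ValidationError("lags must be strictly ascending")
        if (lag <= 0).any():
            raise ValidationError("lags must be positive")
        if not np.isfinite(G).all():
            raise ValidationError("G must be finite")
        object.__setattr__(self, "lag", lag)
        object.__setattr__(self, "G", G)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"lag_s": self.lag, "G": self.G}).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, paired_intensity: float | None = None, label: str = "protein"
    ) -> "FcsCurve":
        df = pd.read_csv(path)
        for col in ("lag_s", "G"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        return cls(
            lag=df["lag_s"].to_numpy(),
            G=df["G"].to_numpy(),
            paired_intensity=paired_intensity,
            label=label,
        )


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


@dataclass
class FrapTraceSet:
    """Raw FRAP traces: bleached ROI, unbleached control, background.

    ``bleach_frame`` is the index of the first post-bleach frame.
    """

    time: np.ndarray
    roi: np.ndarray
    control: np.ndarray
    background: np.ndarray
    bleach_frame: int = DEFAULT_BLEACH_FRAME

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("time", "roi", "control", "background"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
        lengths = {a.shape for a in arrays.values()}
        if len(lengths) != 1 or arrays["time"].ndim != 1:
            raise ValidationError("traces must be 1D arrays of equal length")
        if (arrays["time"] < 0).any():
            raise ValidationError("time must be non-negative")
        if not (np.diff(arrays["time"]) > 0).all():
            raise ValidationError("time must strictly increase")
        if not (0 < self.bleach_frame < len(arrays["time"])):
            raise ValidationError("bleach_frame must fall inside the trace")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "roi": self.roi,
                "control": self.control,
                "background": self.background,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, bleach_frame: int = DEFAULT_BLEACH_FRAME) -> "FrapTraceSet":
        df = pd.read_csv(path)
        for col in ("time_s", "roi", "control", "background"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        return cls(
            time=df["time_s"].to_numpy(),
            roi=df["roi"].to_numpy(),
            control=df["control"].to_numpy(),
            background=df["background"].to_numpy(),
            bleach_frame=bleach_frame,
        )


def load_frap_traces(
    path: str | Path, bleach_frame: int = DEFAULT_BLEACH_FRAME
) -> FrapTraceSet:
    """Read a FRAP trace CSV (``time_s, roi, control, background``)."""
    return FrapTraceSet.from_csv(path, bleach_frame=bleach_frame)


# ---------------------------------------------------------------------------
# Coordinate helpers
# ---------------------------------------------------------------------------


def positions_to_pixels(
    x: np.ndarray, y: np.ndarray, pixel_size: float, shape: tuple[int, int],
    clip: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Map μm coordinates to (row, col) pixel indices.

    Out-of-bounds localizations are clipped to the raster edge with a
    warning when ``clip`` is true, otherwise raise.
    """
    col = np.floor(np.asarray(x) / pixel_size).astype(int)
    row = np.floor(np.asarray(y) / pixel_size).astype(int)
    oob = (row < 0) | (row >= shape[0]) | (col < 0) | (col >= shape[1])
    if oob.any():
        if not clip:
            raise ValidationError("localization outside raster bounds")
        warnings.warn(
            f"{int(oob.sum())} localizations outside raster bounds were clipped",
            stacklevel=2,
        )
        row = np.clip(row, 0, shape[0] - 1)
        col = np.clip(col, 0, shape[1] - 1)
    return row, col
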