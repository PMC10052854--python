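"""Frame-sequence and session-table I/O.

The imaging unit exchanged by every stage is a :class:`FrameSequence`: an
ordered stack of 2-D intensity frames with a frame rate.  Thermal cameras
report surface radiance in arbitrary (instrument) units; nothing downstream
depends on absolute calibration, only on temporal variation, so frames are
held as ``float64`` regardless of the on-disk bit depth.

Image sequences on disk are 8/16-bit grayscale or float PNG/TIFF files, one
file per frame, ordered by the numeric suffix of the filename (zero-padded
counters such as ``frame_000123.png``).  RGB input handed to the thermal
path is reduced to a single channel by an unweighted channel mean, matching
how thermal exports with a black-and-white palette are handled.
"""

from __future__ import annotations

import glob
import json
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "Rect",
    "SessionRecord",
    "read_frames",
    "write_frames",
    "trim",
    "read_session_table",
    "packaged_table1_path",
    "packaged_table2_path",
]

_IMAGE_EXTS = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, half-open: columns [x, x+w), rows [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("Rect width and height must be positive")

    @property
    def area(self) -> int:
        return self.w * self.h

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)

    def within(self, height: int, width: int) -> bool:
        return 0 <= self.x and 0 <= self.y and self.x + self.w <= width and self.y + self.h <= height


@dataclass
class FrameSequence:
    """Ordered stack of 2-D intensity frames (time x height x width) at a fixed rate."""

    frames: np.ndarray
    fps: float
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (time, height, width)")
        if self.frames.shape[0] < 2:
            raise ValueError("at least 2 frames required")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps

    def copy(self) -> "FrameSequence":
        return FrameSequence(self.frames.copy(), self.fps, self.origin_label)


def _numeric_key(path: str) -> tuple:
    """Sort key: trailing numeric suffix of the stem, then the name itself."""
    stem = Path(path).stem
    m = re.search(r"(\d+)$", stem)
    return (int(m.group(1)) if m else -1, stem)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.float64)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[:, :, :3].astype(np.float64).mean(axis=2)
    raise ValueError(f"unsupported image shape {img.shape}")


def read_frames(path_pattern: str | os.PathLike, fps: float = 30.0) -> FrameSequence:
    """Read an image sequence (directory, glob, or single video file).

    Frames are returned in filename order sorted by zero-padded numeric
    suffix (or container order for video files).  RGB frames are reduced to
    grayscale by the unweighted channel mean.

    Parameters
    ----------
    path_pattern
        Directory containing PNG/TIFF frames, a glob over image files, or a
        path to a video container readable by imageio.
    fps
        Frame rate in Hz (image sequences carry no timing metadata).
    """
    p = Path(path_pattern)
    if p.is_dir():
        files: list[str] = []
        for ext in _IMAGE_EXTS:
            files.extend(glob.glob(str(p / f"*{ext}")))
    elif p.is_file() and p.suffix.lower() not in _IMAGE_EXTS:
        # video container
        stack = iio.imread(str(p))
        frames = np.stack([_to_gray(f) for f in stack])
        if frames.shape[0] < 2:
            raise ValueError("at least 2 frames required")
        return FrameSequence(frames, fps=fps, origin_label=str(p))
    else:
        files = glob.glob(str(path_pattern))
    if not files:
        raise FileNotFoundError(f"no frames match {path_pattern!r}")
    files.sort(key=_numeric_key)
    if len(files) < 2:
        raise ValueError("at least 2 frames required")
    imgs = [_to_gray(iio.imread(f)) for f in files]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame dimensions: {sorted(shapes)}")
    return FrameSequence(np.stack(imgs), fps=fps, origin_label=str(path_pattern))


def write_frames(
    seq: FrameSequence,
    out_dir: str | os.PathLike,
    prefix: str = "frame",
    fmt: str = "tiff",
    dtype: np.dtype | type = np.float32,
    sidecar: Optional[dict] = None,
) -> list[Path]:
    """Write one image file per frame plus an optional JSON sidecar.

    Float TIFF (the default) round-trips pixel values losslessly at the
    chosen precision.  For 8/16-bit integer output the caller is responsible
    for the value range.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".tif" if fmt.lower() in ("tif", "tiff") else ".png"
    ndigits = max(4, len(str(seq.n_frames)))
    paths = []
    for i, frame in enumerate(seq.frames):
        path = out / f"{prefix}_{i:0{ndigits}d}{ext}"
        iio.imwrite(path, frame.astype(dtype))
        paths.append(path)
    meta = {"fps": seq.fps, "n_frames": seq.n_frames, "origin_label": seq.origin_label}
    if sidecar:
        meta.update(sidecar)
    (out / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))
    return paths


def trim(seq: FrameSequence, start_s: float, duration_s: float) -> FrameSequence:
    """Half-open temporal crop: floor(duration*fps) frames from floor(start*fps).

    The frame rate is unchanged; trimming never resamples.
    """
    if start_s < 0:
        raise ValueError("start_s must be non-negative")
    if start_s + duration_s > seq.duration_seconds + 1e-9:
        raise ValueError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds clip duration "
            f"{seq.duration_seconds:.3f} s"
        )
    i0 = int(np.floor(start_s * seq.fps))
    n = int(np.floor(duration_s * seq.fps))
    return FrameSequence(seq.frames[i0 : i0 + n].copy(), seq.fps, seq.origin_label)


# ---------------------------------------------------------------------------
# Session tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "species",
    "taxa",
    "immobilized_or_voluntary",
    "color",
    "integument_thick",
    "subcutaneous_fat",
    "quality_score",
    "true_rr",
    "irt_rr",
    "rr_location",
    "true_hr",
    "irt_hr",
    "hr_location",
]


@dataclass
class SessionRecord:
    """One imaging session: covariates, true and IRT-derived vital rates.

    ``true_measured`` marks sessions where a reference (stethoscope/ribcage)
    measurement was obtained, even when its numeric value is not recoverable
    from the transcription; these sessions belong to the validation set.
    Success flags mean a clear IRT peak was extracted, independent of
    whether a true value exists for comparison.
    """

    species: str
    taxa: str  # mammal | bird | reptile
    immobilized: bool
    color: str = ""
    integument_thick: bool = False
    subcutaneous_fat: bool = False
    quality_score: Optional[int] = None
    true_rr: Optional[float] = None
    irt_rr: Optional[float] = None
    rr_location: str = ""
    true_hr: Optional[float] = None
    irt_hr: Optional[float] = None
    hr_location: str = ""
    mass_kg: Optional[float] = None
    true_measured: Optional[bool] = None
    transcription_notes: str = ""

    def __post_init__(self) -> None:
        if self.taxa not in ("mammal", "bird", "reptile"):
            raise ValueError(f"unknown taxa {self.taxa!r} for {self.species}")
        if self.quality_score is not None and not 0 <= self.quality_score <= 8:
            raise ValueError(f"quality_score {self.quality_score} outside 0..8")
        if self.true_measured is None:
            self.true_measured = self.true_rr is not None or self.true_hr is not None

    @property
    def rr_success(self) -> bool:
        return self.irt_rr is not None

    @property
    def hr_success(self) -> bool:
        return self.irt_hr is not None

    @property
    def in_validation_set(self) -> bool:
        return bool(self.true_measured)


def _opt_float(value, row_label: str, col: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed numeric cell {col}={value!r} in row {row_label!r}") from exc


def _opt_bool(value, row_label: str, col: str) -> bool:
    s = str(value).strip().lower()
    if s in ("yes", "true", "1", "thick", "immobilized"):
        return True
    if s in ("no", "false", "0", "thin", "voluntary", "", "nan"):
        return False
    raise ValueError(f"malformed boolean cell {col}={value!r} in row {row_label!r}")


def read_session_table(path: str | os.PathLike) -> list[SessionRecord]:
    """Read a session CSV (one row per imaging session) into records.

    Empty cells become missing values, never zeros.  Raises on a malformed
    numeric cell, naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session table missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        label = row["species"]
        q = _opt_float(row["quality_score"], label, "quality_score")
        tm = row.get("true_measured", "")
        records.append(
            SessionRecord(
                species=row["species"],
                taxa=row["taxa"].strip().lower(),
                immobilized=_opt_bool(row["immobilized_or_voluntary"], label, "immobilized_or_voluntary"),
                color=row["color"],
                integument_thick=_opt_bool(row["integument_thick"], label, "integument_thick"),
                subcutaneous_fat=_opt_bool(row["subcutaneous_fat"], label, "subcutaneous_fat"),
                quality_score=None if q is None else int(q),
                true_rr=_opt_float(row["true_rr"], label, "true_rr"),
                irt_rr=_opt_float(row["irt_rr"], label, "irt_rr"),
                rr_location=row["rr_location"],
                true_hr=_opt_float(row["true_hr"], label, "true_hr"),
                irt_hr=_opt_float(row["irt_hr"], label, "irt_hr"),
                hr_location=row["hr_location"],
                mass_kg=_opt_float(row.get("mass_kg", ""), label, "mass_kg"),
                true_measured=(None if tm == "" else _opt_bool(tm, label, "true_measured")),
                transcription_notes=row.get("transcription_notes", ""),
            )
        )
    return records


def packaged_table1_path() -> Path:
    """Path of the packaged per-session validation table (58 sessions)."""
    return Path(__file__).parent / "data" / "table1.csv"


def packaged_table2_path() -> Path:
    """Path of the packaged group-success summary (printed group sizes and %)."""
    return Path(__file__).parent / "data" / "table2.csv"
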