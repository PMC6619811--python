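"""Raster and dataset I/O: grayscale frames, ROI crops, and CSV manifests.

All computation-bearing steps live in the other modules; this one only moves
pixels and bookkeeping rows between disk and memory.  Manifests are plain CSV
with a fixed column order so they diff cleanly and can be consumed outside
Python.  Box coordinates are 0-based, half-open ``[row_start, row_end) x
[col_start, col_end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "GrayFrame",
    "ManifestRecord",
    "DatasetManifest",
    "load_frame",
    "save_frame",
    "save_roi_set",
    "load_class_directory",
]

#: fixed manifest column order (documented contract, do not reorder)
MANIFEST_COLUMNS = [
    "path",
    "frame_id",
    "roi_id",
    "class_label",
    "split",
    "augmentation_tag",
    "row_start",
    "row_end",
    "col_start",
    "col_end",
]

ALLOWED_SPLITS = frozenset({"train", "test"})

# ITU-R BT.601 luminance weights for deterministic RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayFrame:
    """A single-channel intensity image with an explicit bit depth.

    ``i_max`` is the maximum representable intensity (255 for 8-bit,
    65535 for 16-bit), not the maximum observed value.
    """

    pixels: np.ndarray
    bit_depth: int
    frame_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("frame has zero area")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > self.i_max:
            raise ValueError("intensities outside [0, i_max]")
        object.__setattr__(self, "pixels", px)

    @property
    def i_max(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n(self) -> int:
        return int(self.pixels.size)


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    frame_id: str
    roi_id: str
    class_label: str
    split: str
    augmentation_tag: str = ""
    row_start: int = 0
    row_end: int = 0
    col_start: int = 0
    col_end: int = 0


@dataclass
class DatasetManifest:
    """Ordered collection of dataset rows with validated invariants.

    Invariants: paths are unique, split labels come from {train, test}, and
    no ``roi_id`` appears in both splits (train/test independence).
    """

    records: list[ManifestRecord] = field(default_factory=list)

    def append(self, rec: ManifestRecord) -> None:
        self.records.append(rec)

    def validate(self) -> None:
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths are not unique")
        bad = {r.split for r in self.records} - ALLOWED_SPLITS
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")
        by_split: dict[str, set[str]] = {"train": set(), "test": set()}
        for r in self.records:
            by_split[r.split].add(r.roi_id)
        overlap = by_split["train"] & by_split["test"]
        if overlap:
            raise ValueError(
                f"roi_ids present in both splits: {sorted(overlap)[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in MANIFEST_COLUMNS] for r in self.records],
            columns=MANIFEST_COLUMNS,
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.validate()
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        recs = [
            ManifestRecord(
                path=str(row["path"]),
                frame_id=str(row["frame_id"]),
                roi_id=str(row["roi_id"]),
                class_label=str(row["class_label"]),
                split=str(row["split"]),
                augmentation_tag=str(row["augmentation_tag"]),
                row_start=int(row["row_start"]),
                row_end=int(row["row_end"]),
                col_start=int(row["col_start"]),
                col_end=int(row["col_end"]),
            )
            for _, row in df.iterrows()
        ]
        m = cls(recs)
        m.validate()
        return m

    def __len__(self) -> int:
        return len(self.records)


def _to_gray(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Collapse color planes with BT.601 weights; infer bit depth from dtype."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        depth = 16 if arr.dtype.itemsize >= 2 else 8
        gray = np.round(arr[:, :, :3].astype(np.float64) @ _LUMA)
        gray = np.clip(gray, 0, (1 << depth) - 1)
        return gray.astype(np.uint16 if depth == 16 else np.uint8), depth
    if arr.ndim != 2:
        raise ValueError(f"unsupported image shape {arr.shape}")
    if arr.dtype.itemsize >= 2:
        return arr.astype(np.uint16), 16
    return arr.astype(np.uint8), 8


def load_frame(path: str | os.PathLike) -> GrayFrame:
    """Read a PNG/TIFF raster as a :class:`GrayFrame`.

    Color images are converted to luminance grayscale deterministically;
    16-bit inputs keep their full range (``i_max = 65535``).
    """
    p = Path(path)
    try:
        arr = iio.imread(p)
    except Exception as exc:  # imageio raises various concrete types
        raise IOError(f"cannot read image file {p}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-area image: {p}")
    gray, depth = _to_gray(np.asarray(arr))
    return GrayFrame(pixels=gray, bit_depth=depth, frame_id=p.stem)


def save_frame(frame_or_array, path: str | os.PathLike) -> None:
    arr = frame_or_array.pixels if isinstance(frame_or_array, GrayFrame) else frame_or_array
    iio.imwrite(Path(path), np.asarray(arr))


def save_roi_set(rois: Sequence, out_dir: str | os.PathLike,
                 manifest: DatasetManifest | None = None,
                 split: str = "train") -> list[Path]:
    """Write one PNG per ROI crop plus one manifest row each.

    ``rois`` are :class:`planktonseg.extraction.ROI` objects.  Returns the
    written paths; the manifest (created if not given) gains one row per file.
    Round-tripping through :func:`load_frame` is pixel-exact at 8/16 bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = DatasetManifest()
    ids = [f"{r.frame_id}_{r.roi_id}" for r in rois]
    if len(set(ids)) != len(ids):
        raise ValueError("roi_id collision within frame")
    paths: list[Path] = []
    for roi in rois:
        fname = f"{roi.frame_id}_{roi.roi_id}.png"
        fpath = out / fname
        crop = roi.enhanced_crop if roi.enhanced_crop is not None else roi.gray_crop
        iio.imwrite(fpath, np.asarray(crop))
        manifest.append(ManifestRecord(
            path=str(fpath), frame_id=roi.frame_id, roi_id=roi.roi_id,
            class_label="", split=split, augmentation_tag="",
            row_start=roi.box.row_start, row_end=roi.box.row_end,
            col_start=roi.box.col_start, col_end=roi.box.col_end,
        ))
        paths.append(fpath)
    manifest.validate()
    return paths


def load_class_directory(root: str | os.PathLike) -> dict[str, list[GrayFrame]]:
    """Load a directory-per-class labeled crop layout (class name = dir name)."""
    rootp = Path(root)
    out: dict[str, list[GrayFrame]] = {}
    for cls_dir in sorted(p for p in rootp.iterdir() if p.is_dir()):
        out[cls_dir.name] = [
            load_frame(f) for f in sorted(cls_dir.glob("*.png")) + sorted(cls_dir.glob("*.tif*"))
        ]
    return out
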