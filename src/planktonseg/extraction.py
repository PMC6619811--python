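"""Candidate-target segmentation: adaptive binarization, MSER, boxes, crops.

Two branches, chosen per frame by the contrast router:

* **Sauvola, single-pixel sliding window** — for low-contrast frames.  Every
  pixel is the center of a small window (side 1–3% of the frame dimension)
  and gets its own local threshold

      T = m * (1 + k * (sigma / R - 1))

  with window mean ``m``, window (population) standard deviation ``sigma``,
  fixed coefficient ``k`` (0.34) and maximum possible standard deviation
  ``R`` (128 for 8-bit grayscale).  In flat regions T drops well below the
  local mean; where contrast is high sigma approaches R and T approaches m.
  Bright-foreground polarity marks pixels strictly above their threshold.

* **MSER** — for high-contrast frames: maximally stable extremal regions
  computed on the component tree (max-tree), selecting components whose area
  changes slowly across an intensity range ``delta``.

Downstream, binary masks are reduced to 8-connected components, small
components are dropped, nearby/overlapping boxes are merged to a fixed point
(a declared IoU/gap union rule standing in for learned region-proposal
merging), and crops are cut from the frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import max_tree

from .contrast import DEFAULT_MSNR_THRESHOLD, Route, compute_msnr
from .image_io import GrayFrame

__all__ = [
    "Polarity",
    "SauvolaParams",
    "MSERConfig",
    "BoundingBox",
    "ROI",
    "ExtractionConfig",
    "window_side",
    "sauvola_threshold",
    "binarize_sliding",
    "mser_regions",
    "connected_components",
    "merge_boxes",
    "extract_rois",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


class Polarity(str, enum.Enum):
    BRIGHT_FG = "bright"  # targets brighter than background (dark-field in situ)
    DARK_FG = "dark"      # classical document polarity


@dataclass(frozen=True)
class SauvolaParams:
    k: float = 0.34
    R: float = 128.0
    window_frac: float = 0.02
    polarity: Polarity = Polarity.BRIGHT_FG

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if not (0.01 <= self.window_frac <= 0.03):
            raise ValueError("window_frac must lie in [0.01, 0.03]")


@dataclass(frozen=True)
class MSERConfig:
    delta: int = 5                 # intensity range over which stability is measured
    min_area: int = 25
    max_area_frac: float = 0.25    # regions larger than this fraction of the frame are dropped
    max_variation: float = 0.5
    min_diversity: float = 0.2     # nested regions closer in area than this are deduplicated
    polarity: Polarity = Polarity.BRIGHT_FG


@dataclass(frozen=True, order=True)
class BoundingBox:
    """0-based half-open pixel bounds [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    col_start: int
    row_end: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("empty bounding box")

    @property
    def area(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)

    def union(self, other: "BoundingBox") -> "BoundingBox":
        return BoundingBox(
            min(self.row_start, other.row_start),
            min(self.col_start, other.col_start),
            max(self.row_end, other.row_end),
            max(self.col_end, other.col_end),
        )

    def intersection_area(self, other: "BoundingBox") -> int:
        h = min(self.row_end, other.row_end) - max(self.row_start, other.row_start)
        w = min(self.col_end, other.col_end) - max(self.col_start, other.col_start)
        return h * w if (h > 0 and w > 0) else 0

    def iou(self, other: "BoundingBox") -> float:
        inter = self.intersection_area(other)
        return inter / (self.area + other.area - inter)

    def gaps(self, other: "BoundingBox") -> tuple[int, int]:
        """(row gap, col gap) between box edges; 0 where the axis intervals overlap."""
        rg = max(self.row_start, other.row_start) - min(self.row_end, other.row_end)
        cg = max(self.col_start, other.col_start) - min(self.col_end, other.col_end)
        return max(rg, 0), max(cg, 0)


@dataclass
class ROI:
    box: BoundingBox
    gray_crop: np.ndarray
    mask_crop: np.ndarray
    method: Route
    frame_id: str
    roi_id: str
    enhanced_crop: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.box.row_end - self.box.row_start,
                 self.box.col_end - self.box.col_start)
        if self.gray_crop.shape != shape or self.mask_crop.shape != shape:
            raise ValueError("crop shapes do not match the bounding box")
        if not self.mask_crop.any():
            raise ValueError("mask_crop has no foreground pixel")


def window_side(dim: int, window_frac: float) -> int:
    """Sliding-window side: round(frac * dim), forced odd, floor 3."""
    side = int(round(window_frac * dim))
    side = max(side, 3)
    if side % 2 == 0:
        side += 1
    return side


def sauvola_threshold(window_pixels: np.ndarray, params: SauvolaParams = SauvolaParams()) -> float:
    """Local threshold T = m(1 + k(sigma/R - 1)) for one window.

    ``sigma`` uses the population (divide-by-count) convention, matching the
    bounded-by-R framing (R is the largest standard deviation a grayscale
    window can attain).
    """
    w = np.asarray(window_pixels, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty window")
    m = float(w.mean())
    sigma = float(np.sqrt(np.maximum((w ** 2).mean() - m * m, 0.0)))
    return m * (1.0 + params.k * (sigma / params.R - 1.0))


def _clipped_box_stats(px: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and population std over windows clipped at frame edges.

    Integral images in float64: window sums of integer intensities are exact
    for 8-bit frames of any practical size.
    """
    h, w = px.shape
    a = px.astype(np.float64)
    ii = np.zeros((h + 1, w + 1))
    ii[1:, 1:] = a.cumsum(0).cumsum(1)
    ii2 = np.zeros((h + 1, w + 1))
    ii2[1:, 1:] = (a * a).cumsum(0).cumsum(1)

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r0 = np.clip(rows - radius, 0, h)
    r1 = np.clip(rows + radius + 1, 0, h)
    c0 = np.clip(cols - radius, 0, w)
    c1 = np.clip(cols + radius + 1, 0, w)
    def boxsum(I):
        return (I[r1, c1] - I[r0, c1] - I[r1, c0] + I[r0, c0])
    count = (r1 - r0) * (c1 - c0)
    s = boxsum(ii)
    s2 = boxsum(ii2)
    mean = s / count
    var = np.maximum(s2 / count - mean * mean, 0.0)
    return mean, np.sqrt(var)


def binarize_sliding(frame: GrayFrame, params: SauvolaParams = SauvolaParams(),
                     stride: int = 1) -> np.ndarray:
    """Single-pixel sliding Sauvola binarization.

    Each pixel is the center of its own window (clipped at frame edges;
    statistics over the intersection) and is marked foreground according to
    ``params.polarity`` (BRIGHT_FG: pixel strictly above its threshold).
    ``stride`` > 1 evaluates thresholds on a subsampled grid and reuses the
    nearest grid threshold in between — an acceleration only; the default
    stride of 1 matches the per-pixel definition exactly.
    """
    px = frame.pixels
    side = window_side(min(frame.height, frame.width), params.window_frac)
    if min(frame.height, frame.width) < 3:
        raise ValueError("frame smaller than the minimum 3x3 window")
    radius = side // 2
    if stride == 1:
        mean, sigma = _clipped_box_stats(px, radius)
        thresh = mean * (1.0 + params.k * (sigma / params.R - 1.0))
    else:
        mean, sigma = _clipped_box_stats(px, radius)
        t = mean * (1.0 + params.k * (sigma / params.R - 1.0))
        tg = t[::stride, ::stride]
        thresh = np.repeat(np.repeat(tg, stride, axis=0), stride, axis=1)
        thresh = thresh[: px.shape[0], : px.shape[1]]
    if params.polarity is Polarity.BRIGHT_FG:
        return px > thresh
    return px < thresh


# ---------------------------------------------------------------------------
# MSER on the max-tree
# ---------------------------------------------------------------------------

def mser_regions(frame: GrayFrame, config: MSERConfig = MSERConfig()) -> list[np.ndarray]:
    """Maximally stable extremal regions as boolean masks.

    Built on the component tree (max-tree).  For a component ``C_l`` whose
    canonical level is ``l``, stability is the relative area growth

        variation = (|C_{l-delta}| - |C_l|) / |C_l|

    where ``C_{l-delta}`` is the connected component of ``pixels >= l-delta``
    containing ``C_l`` (its ancestor in the tree).  Components within the
    area bounds whose variation does not exceed ``max_variation`` are
    selected; nested selections with relative area difference below
    ``min_diversity`` are deduplicated keeping the more stable one.
    Bright-on-dark regions by default; DARK_FG inverts the image first.
    """
    px = frame.pixels
    if config.polarity is Polarity.DARK_FG:
        px = frame.i_max - px
    flat = px.ravel().astype(np.int64)
    n = flat.size
    parent_img, traverser = max_tree(px, connectivity=2)
    parent = parent_img.ravel()
    root = traverser[0]

    area = np.ones(n, dtype=np.int64)
    for node in traverser[:0:-1]:       # children before parents
        area[parent[node]] += area[node]

    canonical = flat[parent] != flat
    canonical[root] = True
    cano_nodes = np.flatnonzero(canonical)

    max_area = config.max_area_frac * n
    variation = {}
    for nd in cano_nodes:
        if nd == root:
            continue
        a = area[nd]
        if a < config.min_area or a > max_area:
            continue
        lvl = flat[nd]
        # climb to the ancestor whose canonical level is the smallest >= lvl-delta:
        # that node's component equals the threshold component at lvl-delta
        anc = nd
        while anc != root and flat[parent[anc]] >= lvl - config.delta:
            anc = parent[anc]
        var = (area[anc] - a) / a
        if var <= config.max_variation:
            variation[int(nd)] = float(var)

    # diversity pruning: ancestors first (largest area)
    kept: dict[int, float] = {}
    order = sorted(variation, key=lambda nd: -area[nd])
    for nd in order:
        anc = parent[nd]
        drop = False
        while True:
            if anc in kept:
                a_big, a_small = area[anc], area[nd]
                if (a_big - a_small) / a_big < config.min_diversity:
                    if variation[nd] < kept[anc]:
                        del kept[anc]
                    else:
                        drop = True
                break
            if anc == root:
                break
            anc = parent[anc]
        if not drop:
            kept[nd] = variation[nd]

    masks: list[np.ndarray] = []
    for nd in sorted(kept):
        lvl = flat[nd]
        lab, _ = ndimage.label(px >= lvl, structure=_EIGHT)
        r, c = divmod(int(nd), px.shape[1])
        masks.append(lab == lab[r, c])
    return masks


def connected_components(mask: np.ndarray, min_area: int = 25) -> list[BoundingBox]:
    """Tight bounding boxes of 8-connected foreground components with area >= min_area."""
    lab, nlab = ndimage.label(np.asarray(mask, dtype=bool), structure=_EIGHT)
    if nlab == 0:
        return []
    areas = np.bincount(lab.ravel())
    boxes = []
    for i, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None or areas[i] < min_area:
            continue
        boxes.append(BoundingBox(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop))
    return sorted(boxes)


def _mergeable(a: BoundingBox, b: BoundingBox, iou_merge: float, gap_px: int) -> bool:
    if a.iou(b) >= iou_merge:
        return True
    rg, cg = a.gaps(b)
    return rg <= gap_px and cg <= gap_px


def merge_boxes(boxes: Sequence[BoundingBox], iou_merge: float = 0.2,
                gap_px: int = 2) -> list[BoundingBox]:
    """Union-merge overlapping/nearby boxes to a fixed point.

    At each round a graph is built over current boxes with an edge wherever a
    pair overlaps with IoU >= ``iou_merge`` or has both edge gaps <=
    ``gap_px``; every connected group collapses to its union box.  Rounds
    repeat until nothing merges, so the result is independent of input order
    and pairwise fails both criteria.
    """
    current = sorted(boxes)
    while True:
        k = len(current)
        if k <= 1:
            return current
        # union-find over the mergeable graph
        up = list(range(k))

        def find(i):
            while up[i] != i:
                up[i] = up[up[i]]
                i = up[i]
            return i

        merged_any = False
        for i in range(k):
            for j in range(i + 1, k):
                if _mergeable(current[i], current[j], iou_merge, gap_px):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        up[rj] = ri
                        merged_any = True
        if not merged_any:
            return current
        groups: dict[int, BoundingBox] = {}
        for i in range(k):
            r = find(i)
            groups[r] = current[i] if r not in groups else groups[r].union(current[i])
        current = sorted(groups.values())


@dataclass(frozen=True)
class ExtractionConfig:
    msnr_threshold: float = DEFAULT_MSNR_THRESHOLD
    sauvola: SauvolaParams = field(default_factory=SauvolaParams)
    mser: MSERConfig = field(default_factory=MSERConfig)
    denoise_window_frac: float = 0.02
    apply_denoise: bool = True
    min_area: int = 25
    iou_merge: float = 0.2
    gap_px: int | None = None      # None -> half the Sauvola window side


def extract_rois(frame: GrayFrame, config: ExtractionConfig = ExtractionConfig()) -> list[ROI]:
    """Full single-frame segmentation: route, binarize, denoise, box, merge, crop."""
    # local import: enhancement depends on nothing here, but keep modules acyclic
    from .enhancement import DenoiseParams, denoise_roughen

    report = compute_msnr(frame, threshold=config.msnr_threshold)
    if report.route is Route.SAUVOLA:
        mask = binarize_sliding(frame, config.sauvola)
    else:
        regions = mser_regions(frame, config.mser)
        mask = np.zeros(frame.pixels.shape, dtype=bool)
        for m in regions:
            mask |= m
    if config.apply_denoise:
        mask = denoise_roughen(mask, DenoiseParams(window_frac=config.denoise_window_frac))
    boxes = connected_components(mask, min_area=config.min_area)
    side = window_side(min(frame.height, frame.width), config.sauvola.window_frac)
    gap = config.gap_px if config.gap_px is not None else side // 2
    boxes = merge_boxes(boxes, iou_merge=config.iou_merge, gap_px=gap)
    rois = []
    for i, b in enumerate(sorted(boxes)):
        mask_crop = mask[b.row_start:b.row_end, b.col_start:b.col_end]
        if not mask_crop.any():
            continue  # merging can in principle cover only-background area
        rois.append(ROI(
            box=b,
            gray_crop=frame.pixels[b.row_start:b.row_end, b.col_start:b.col_end].copy(),
            mask_crop=mask_crop.copy(),
            method=report.route,
            frame_id=frame.frame_id,
            roi_id=f"r{i:03d}",
        ))
    return rois
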