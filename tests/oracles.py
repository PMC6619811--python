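"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: windows are
sliced per pixel, variance is the classic two-pass formula, clusters are
grown by an explicit flood fill.
"""

from __future__ import annotations

import math

import numpy as np

from planktonseg.extraction import Polarity, window_side


def brute_force_sauvola_mask(pixels: np.ndarray, k: float = 0.34, R: float = 128.0,
                             window_frac: float = 0.02,
                             polarity: Polarity = Polarity.BRIGHT_FG) -> np.ndarray:
    """Per-pixel sliding Sauvola with clipped windows, one window at a time."""
    h, w = pixels.shape
    side = window_side(min(h, w), window_frac)
    rad = side // 2
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            win = pixels[max(r - rad, 0):r + rad + 1,
                         max(c - rad, 0):c + rad + 1].astype(np.float64)
            m = win.mean()
            sigma = math.sqrt(((win - m) ** 2).mean())
            t = m * (1.0 + k * (sigma / R - 1.0))
            if polarity is Polarity.BRIGHT_FG:
                out[r, c] = pixels[r, c] > t
            else:
                out[r, c] = pixels[r, c] < t
    return out


def flood_fill_clusters(mask: np.ndarray) -> list[int]:
    """Sizes of 8-connected foreground clusters via explicit BFS."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    seen = np.zeros_like(m)
    sizes = []
    for r in range(h):
        for c in range(w):
            if not m[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and m[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            sizes.append(size)
    return sizes


def brute_force_denoise(mask: np.ndarray, window_frac: float = 0.02,
                        cluster_frac: float = 0.75) -> np.ndarray:
    """Literal evaluation of the valid-pixel + clustering rule at every pixel."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    side = window_side(min(h, w), window_frac)
    rad = side // 2
    s = math.isqrt(side * side)
    t_value = math.isqrt(2 * s * s) - 2
    out = np.zeros_like(m)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(r - rad, 0), min(r + rad + 1, h)
            c0, c1 = max(c - rad, 0), min(c + rad + 1, w)
            n_valid = int(m[r0:r1, c0:c1].sum())
            if n_valid < t_value:
                continue
            need = cluster_frac * n_valid
            regions = [
                (r0, r1, c0, c1),
                (max(r - rad - side, 0), r1, c0, c1),
                (r0, min(r + rad + 1 + side, h), c0, c1),
                (r0, r1, max(c - rad - side, 0), c1),
                (r0, r1, c0, min(c + rad + 1 + side, w)),
            ]
            for a, b, d, e in regions:
                sizes = flood_fill_clusters(m[a:b, d:e])
                if sizes and max(sizes) >= need:
                    out[r, c] = True
                    break
    return out


def brute_force_boxes(mask: np.ndarray, min_area: int) -> list[tuple[int, int, int, int]]:
    """Tight boxes of 8-connected components via the BFS flood fill."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    seen = np.zeros_like(m)
    boxes = []
    for r in range(h):
        for c in range(w):
            if not m[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            pix = []
            while stack:
                rr, cc = stack.pop()
                pix.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and m[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            if len(pix) >= min_area:
                rs = [p[0] for p in pix]
                cs = [p[1] for p in pix]
                boxes.append((min(rs), min(cs), max(rs) + 1, max(cs) + 1))
    return sorted(boxes)
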