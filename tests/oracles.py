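"""Brute-force reference implementations used to validate the fast paths.

Every function here is a direct double-loop transcription of the pixel
rules, independent of the vectorised implementations in camvessel.
"""

from __future__ import annotations

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Offsets of the disk footprint: dx^2 + dy^2 <= r^2 (matches skimage disk)."""
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def bernsen_oracle(
    pixels: np.ndarray, radius: int, contrast_min: float, invert: bool = False
) -> np.ndarray:
    """Per-pixel Bernsen rule with symmetric (reflective) border padding."""
    padded = np.pad(pixels, radius, mode="symmetric")
    h, w = pixels.shape
    out = np.zeros((h, w), dtype=np.uint8)
    offsets = disk_offsets(radius)
    for i in range(h):
        for j in range(w):
            vals = [padded[i + radius + dy, j + radius + dx] for dy, dx in offsets]
            lo, hi = min(vals), max(vals)
            if hi - lo < contrast_min:
                continue
            threshold = (hi + lo) / 2.0
            value = pixels[i, j]
            if (value > threshold) if invert else (value < threshold):
                out[i, j] = 1
    return out


def median3_oracle(pixels: np.ndarray) -> np.ndarray:
    """3x3 median with symmetric border padding."""
    padded = np.pad(pixels, 1, mode="symmetric")
    h, w = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(padded[i : i + 3, j : j + 3])
    return out


def diffusion_step_oracle(pixels: np.ndarray, kappa: float, step: float) -> np.ndarray:
    """One explicit Perona-Malik update, edge-replicated borders."""
    padded = np.pad(pixels, 1, mode="edge")
    h, w = pixels.shape
    out = pixels.astype(float).copy()
    for i in range(h):
        for j in range(w):
            c = pixels[i, j]
            flux = 0.0
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                g = padded[i + 1 + di, j + 1 + dj] - c
                flux += np.exp(-((g / kappa) ** 2)) * g
            out[i, j] = c + step * flux
    return out


def classify_oracle(skeleton: np.ndarray) -> tuple[int, int, int]:
    """(endpoints, mids, junctions) by double-loop 8-neighbour counting."""
    s = skeleton.astype(bool)
    h, w = s.shape
    n_end = n_mid = n_junc = 0
    for i in range(h):
        for j in range(w):
            if not s[i, j]:
                continue
            n = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and s[ii, jj]:
                        n += 1
            if n < 2:
                n_end += 1
            elif n == 2:
                n_mid += 1
            else:
                n_junc += 1
    return n_end, n_mid, n_junc


def area_oracle(mask: np.ndarray) -> int:
    """Explicit double-loop foreground count."""
    count = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                count += 1
    return count


def opening_oracle(mask: np.ndarray, radius: int) -> np.ndarray:
    """Disk opening with out-of-frame treated as foreground during erosion."""
    offsets = disk_offsets(radius)
    h, w = mask.shape
    m = mask.astype(bool)
    eroded = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for dy, dx in offsets:
                ii, jj = i + dy, j + dx
                if 0 <= ii < h and 0 <= jj < w and not m[ii, jj]:
                    ok = False
                    break
            eroded[i, j] = ok and m[i, j]
    dilated = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if not eroded[i, j]:
                continue
            for dy, dx in offsets:
                ii, jj = i + dy, j + dx
                if 0 <= ii < h and 0 <= jj < w:
                    dilated[ii, jj] = True
    return dilated
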