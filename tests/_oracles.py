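"""Independent brute-force oracles used across the test suite.

These deliberately re-derive results by enumeration or direct summation,
without calling the package's optimized code paths.
"""

from __future__ import annotations

import numpy as np


def brute_force_maxima(img: np.ndarray, prominence: float) -> list[tuple[int, int]]:
    """Enumerate local maxima by looping over every pixel.

    A pixel qualifies iff its value is >= every 8-neighbour (borders compare
    against the clamped-edge neighbourhood) and strictly exceeds the
    prominence threshold; of each connected equal-valued group of qualifying
    pixels only the smallest (y, x) survives.
    """
    img = np.asarray(img, float)
    h, w = img.shape
    cand = set()
    for y in range(h):
        for x in range(w):
            v = img[y, x]
            if not v > prominence:
                continue
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny = min(max(y + dy, 0), h - 1)
                    nx = min(max(x + dx, 0), w - 1)
                    if img[ny, nx] > v:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                cand.add((y, x))
    # collapse equal-valued touching candidates to their smallest (y, x)
    out = []
    seen = set()
    for y, x in sorted(cand):
        if (y, x) in seen:
            continue
        group = [(y, x)]
        stack = [(y, x)]
        seen.add((y, x))
        while stack:
            cy, cx = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    n = (cy + dy, cx + dx)
                    if n in cand and n not in seen and img[n] == img[cy, cx]:
                        seen.add(n)
                        group.append(n)
                        stack.append(n)
        out.append(min(group))
    return sorted(out)


def circular_roi_mean(img: np.ndarray, cy: int, cx: int, diameter: int = 5) -> float:
    """Mean over pixels whose centres lie within diameter/2 of (cy, cx)."""
    img = np.asarray(img, float)
    r2 = (diameter / 2.0) ** 2
    m = diameter // 2
    vals = []
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            if dy * dy + dx * dx <= r2:
                y, x = cy + dy, cx + dx
                if 0 <= y < img.shape[0] and 0 <= x < img.shape[1]:
                    vals.append(img[y, x])
    return float(np.mean(vals))


def dense_dog_convolution(img: np.ndarray, sigma_small: float, sigma_large: float) -> np.ndarray:
    """Direct (non-FFT, non-ndimage) DOG via explicit separable convolution
    with sampled, normalized Gaussian kernels truncated at 4 sigma and
    reflective boundaries."""
    img = np.asarray(img, float)

    def kernel(sigma):
        r = int(4.0 * sigma + 0.5)
        x = np.arange(-r, r + 1, dtype=float)
        k = np.exp(-(x**2) / (2.0 * sigma**2))
        return k / k.sum(), r

    def conv1d_reflect(arr, k, r, axis):
        arr = np.moveaxis(arr, axis, 0)
        n = arr.shape[0]
        out = np.zeros_like(arr)
        for i in range(n):
            acc = np.zeros(arr.shape[1:])
            for j, kv in enumerate(k):
                idx = i + j - r
                # scipy 'reflect' boundary: (d c b a | a b c d | d c b a)
                while idx < 0 or idx >= n:
                    idx = -idx - 1 if idx < 0 else 2 * n - idx - 1
                acc += kv * arr[idx]
            out[i] = acc
        return np.moveaxis(out, 0, axis)

    def blur(sigma):
        k, r = kernel(sigma)
        return conv1d_reflect(conv1d_reflect(img, k, r, 0), k, r, 1)

    return blur(sigma_small) - blur(sigma_large)
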