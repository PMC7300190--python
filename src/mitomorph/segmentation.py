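"""Pre-processing and binarization of mitochondrial network images.

The morphology pipeline sharpens each z-slice with an unsharp mask,
computes an automatic threshold on the 256-bin gray-level histogram
(Huang's fuzzy-entropy minimizer for the mitochondrial channel, the
IsoData intermeans fixed point for immunofluorescence quantification),
and cleans the resulting one-bit image by removing small and, optionally,
border-touching components.

Both threshold algorithms operate on gray levels 0..255.  Real-valued
images are binned by min–max scaling; the returned threshold is mapped
back to the original intensity scale.  Foreground is strictly greater
than the threshold.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import segmentation as skseg
from skimage.measure import label as sk_label

from .core import BinaryMask, CalibratedImage

__all__ = [
    "unsharp_mask",
    "gray_histogram",
    "huang_threshold",
    "isodata_threshold",
    "threshold_image",
    "binarize_and_clean",
    "max_project",
]


def unsharp_mask(img: CalibratedImage, sigma_px: float = 1.0, weight: float = 0.6) -> CalibratedImage:
    """Sharpen by subtracting a weighted Gaussian blur, slice-wise on stacks.

    output = (I − weight · G_sigma(I)) / (1 − weight), clipped to the valid
    intensity range ([0, ceiling] for images with a declared bit depth or
    integer dtype, non-negative otherwise).
    """
    if not 0 <= weight < 1:
        raise ValueError("weight must lie in [0, 1)")
    if not sigma_px > 0:
        raise ValueError("sigma_px must be positive")
    data = img.pixels.astype(np.float64)
    if img.is_stack:
        blurred = np.stack([ndi.gaussian_filter(s, sigma_px, mode="reflect") for s in data])
    else:
        blurred = ndi.gaussian_filter(data, sigma_px, mode="reflect")
    out = (data - weight * blurred) / (1.0 - weight)
    ceiling = img.intensity_ceiling
    out = np.clip(out, 0.0, ceiling if ceiling is not None else None)
    return CalibratedImage(out, img.pixel_size_um, channel=img.channel, bit_depth=img.bit_depth)


def gray_histogram(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin gray-level histogram of an image.

    Integer images already confined to 0..255 are histogrammed directly.
    Anything else is min–max scaled onto gray levels 0..255.  Returns
    ``(counts, vmin, vmax)`` where gray level ``g`` maps back to intensity
    ``vmin + g * (vmax - vmin) / 255``.
    """
    flat = np.asarray(pixels).ravel()
    vmin, vmax = float(flat.min()), float(flat.max())
    if np.issubdtype(flat.dtype, np.integer) and vmin >= 0 and vmax <= 255:
        counts = np.bincount(flat.astype(np.int64), minlength=256)[:256]
        return counts.astype(np.int64), 0.0, 255.0
    if vmax == vmin:
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = flat.size
        return counts, vmin, vmax
    levels = np.clip(((flat - vmin) / (vmax - vmin) * 255.0).round().astype(np.int64), 0, 255)
    return np.bincount(levels, minlength=256), vmin, vmax


def _check_histogram(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonempty bins")
    return hist


def huang_threshold(hist: Sequence[float]) -> int:
    """Gray level minimizing Huang–Wang fuzziness.

    For each candidate t the image is split into background (levels <= t)
    and foreground (> t) with class means mu0, mu1.  Each gray level's
    membership in its class is u(g) = 1 / (1 + |g - mu_class| / C) with C
    the occupied gray-level range, and the candidate minimizing the Shannon
    entropy  -sum h(g) [u ln u + (1-u) ln(1-u)]  is returned.
    """
    hist = _check_histogram(hist)
    g = np.arange(256, dtype=np.float64)
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    C = float(hi - lo)

    csum = np.cumsum(hist)
    cmom = np.cumsum(hist * g)
    total, tmom = csum[-1], cmom[-1]

    entropies = np.full(256, np.inf)
    for t in range(lo, hi):
        w0, m0 = csum[t], cmom[t]
        w1, m1 = total - w0, tmom - m0
        mu0 = m0 / w0
        mu1 = m1 / w1
        mu = np.where(g <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(g - mu) / C)
        # u in (0.5, 1]; the (1-u) log term vanishes at u == 1
        v = 1.0 - u
        ent = -(u * np.log(u) + np.where(v > 0, v * np.log(np.maximum(v, 1e-300)), 0.0))
        entropies[t] = float(np.dot(hist, ent))
    # tie-break: middle of the minimizing plateau (well-separated spikes give a
    # flat zero-fuzziness region; the midpoint splits them symmetrically)
    minimizers = np.nonzero(entropies == entropies.min())[0]
    return int(minimizers[len(minimizers) // 2])


def isodata_threshold(hist: Sequence[float]) -> int:
    """Iterative intermeans (IsoData) threshold on a 256-bin histogram.

    Starting from the global mean, iterate T <- (mean(levels <= T) +
    mean(levels > T)) / 2 until the integer level is a fixed point.
    """
    hist = _check_histogram(hist)
    g = np.arange(256, dtype=np.float64)
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    csum = np.cumsum(hist)
    cmom = np.cumsum(hist * g)
    total, tmom = csum[-1], cmom[-1]

    t = int(np.floor(tmom / total))
    t = min(max(t, lo), hi - 1)
    seen = set()
    while t not in seen:
        seen.add(t)
        w0, m0 = csum[t], cmom[t]
        w1, m1 = total - w0, tmom - m0
        t_new = int(np.floor((m0 / w0 + m1 / w1) / 2.0))
        t_new = min(max(t_new, lo), hi - 1)
        if t_new == t:
            break
        t = t_new
    return t


def threshold_image(
    img: CalibratedImage,
    method: Literal["huang", "isodata"] = "huang",
    per_slice: bool = True,
) -> list[float]:
    """Automatic threshold(s) in original intensity units.

    Returns one threshold per slice when ``per_slice`` (default for the
    morphology pipeline), else a single global threshold repeated for
    every slice.
    """
    fn = {"huang": huang_threshold, "isodata": isodata_threshold}[method]

    def _one(pixels: np.ndarray) -> float:
        hist, vmin, vmax = gray_histogram(pixels)
        level = fn(hist)
        if vmax == 255.0 and vmin == 0.0:
            return float(level)
        return vmin + level * (vmax - vmin) / 255.0

    if img.is_stack and per_slice:
        return [_one(s) for s in img.pixels]
    t = _one(img.pixels)
    return [t] * img.n_slices


def binarize_and_clean(
    img: CalibratedImage,
    threshold: float | Sequence[float],
    min_area_px: int = 0,
    clear_border: bool = False,
) -> BinaryMask:
    """Threshold (strictly greater) then remove aberrantly detected objects.

    8-connected components smaller than ``min_area_px`` are dropped;
    optionally components touching the image border are dropped too.
    Stacks are processed slice-wise.
    """
    if min_area_px < 0:
        raise ValueError("min_area_px must be non-negative")
    thr = np.atleast_1d(np.asarray(threshold, dtype=np.float64))
    if img.is_stack and thr.size == 1:
        thr = np.repeat(thr, img.n_slices)

    def _clean(sl: np.ndarray, t: float) -> np.ndarray:
        m = sl > t
        if min_area_px > 1 and m.any():
            lab = sk_label(m, connectivity=2)
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_area_px  # components with area < min_area are dropped
            keep[0] = False
            m = keep[lab]
        if clear_border and m.any():
            m = skseg.clear_border(m)
        return m

    if img.is_stack:
        mask = np.stack([_clean(s, t) for s, t in zip(img.pixels, thr)])
    else:
        mask = _clean(img.pixels, float(thr[0]))
    prov = {
        "threshold": [float(t) for t in thr] if img.is_stack else float(thr[0]),
        "min_area_px": int(min_area_px),
        "clear_border": bool(clear_border),
        "foreground": "strictly greater than threshold",
        "connectivity": 8,
    }
    return BinaryMask(mask, img.pixel_size_um, provenance=prov)


def max_project(zstack: CalibratedImage) -> CalibratedImage:
    """Per-pixel maximum-intensity projection of a z-stack."""
    if not zstack.is_stack:
        raise ValueError("max_project requires a 3D z-stack")
    return CalibratedImage(
        zstack.pixels.max(axis=0),
        zstack.pixel_size_um,
        channel=zstack.channel,
        bit_depth=zstack.bit_depth,
    )
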