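"""Per-object shape descriptors of segmented mitochondrial particles.

Each 8-connected component of a binary mask yields one record with the
nine descriptors used by particle analysis of mitochondrial networks:
area, perimeter, major/minor axis, angle, aspect ratio, circularity,
roundness and solidity, all in physical units.

Conventions (recorded here because digitized perimeters are not unique):

* ``area`` is the pixel count times the squared pixel size.
* ``perimeter`` is the length of the crack (pixel-edge) boundary, with
  digitization *staircase* corners — a convex corner immediately adjacent
  to a concave or diagonal-contact corner — smoothed by replacing the two
  half-edges at the corner with a diagonal chord (each smoothed corner
  shortens the walk by 2−√2).  Isolated right-angle corners are kept, so
  axis-aligned rectangles measure their exact edge length while rasterized
  disks approach the true circle perimeter.  Hole boundaries are included.
* The fitted ellipse has the component's second central moments and is
  rescaled so its area equals the particle area (the particle-analysis
  convention); ``angle`` is the major-axis direction versus the image
  x-axis, counter-clockwise with y pointing up, in [0, 180).
* ``circularity`` = 4π·area/perimeter² and ``roundness`` =
  4·area/(π·major²) are capped at 1; ``solidity`` = area / convex area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as sk_label, regionprops

from .core import BinaryMask

__all__ = [
    "ParticleRecord",
    "staircase_perimeter",
    "fit_ellipse",
    "measure_particles",
    "particle_table",
]

PARAMETER_NAMES = (
    "area",
    "perimeter",
    "major_axis",
    "minor_axis",
    "angle",
    "aspect_ratio",
    "circularity",
    "roundness",
    "solidity",
)

_CORNER_CUT = 2.0 - math.sqrt(2.0)
_K33 = np.ones((3, 3), dtype=bool)


@dataclass
class ParticleRecord:
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    angle: float
    aspect_ratio: float
    circularity: float
    roundness: float
    solidity: float
    subject: str = ""
    group: str = ""
    treatment: str = ""
    fov: int = 0
    z_slice: int = 0


def staircase_perimeter(mask: np.ndarray) -> float:
    """Crack-boundary length in pixels with staircase corners smoothed."""
    m = np.pad(np.asarray(mask, dtype=np.int8), 1)
    n_edges = int(np.abs(np.diff(m, axis=0)).sum() + np.abs(np.diff(m, axis=1)).sum())
    tl, tr, bl, br = m[:-1, :-1], m[:-1, 1:], m[1:, :-1], m[1:, 1:]
    w = tl + tr + bl + br
    convex = w == 1
    concave = w == 3
    diag = (w == 2) & (((tl == 1) & (br == 1)) | ((tr == 1) & (bl == 1)))
    n_cut = int(
        (convex & ndi.binary_dilation(concave | diag, _K33)).sum()
        + (concave & ndi.binary_dilation(convex | diag, _K33)).sum()
        + 2 * diag.sum()
    )
    return n_edges - n_cut * _CORNER_CUT


def fit_ellipse(coords: np.ndarray, calibration: float = 1.0) -> tuple[float, float, float]:
    """Area-preserving moment ellipse of a pixel set.

    ``coords`` is an (n, 2) array of (row, col) pixel coordinates.  Returns
    (major, minor, angle_degrees) with axes in calibrated units.  Collinear
    pixel sets get a degenerate minor axis chosen so the ellipse area still
    equals the pixel area; a single pixel is rejected.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("ellipse fit requires at least 2 pixels")
    n = coords.shape[0]
    y = coords[:, 0]
    x = coords[:, 1]
    mu20 = np.var(x)
    mu02 = np.var(y)
    mu11 = np.mean((x - x.mean()) * (y - y.mean()))
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4.0 * mu11 ** 2, 0.0))
    l1 = (mu20 + mu02 + common) / 2.0
    l2 = (mu20 + mu02 - common) / 2.0
    major0 = 4.0 * math.sqrt(max(l1, 0.0))
    minor0 = 4.0 * math.sqrt(max(l2, 0.0))
    area_px = float(n)
    if minor0 <= 1e-12:  # collinear: keep the moment major axis, fill minor from area
        major = major0
        minor = 4.0 * area_px / (math.pi * major0) if major0 > 0 else 0.0
    else:
        s = math.sqrt(4.0 * area_px / (math.pi * major0 * minor0))
        major, minor = major0 * s, minor0 * s
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)  # x right, y down
    angle = (-math.degrees(theta)) % 180.0  # report with y up
    return major * calibration, minor * calibration, angle


def _measure_slice(
    mask2d: np.ndarray,
    cal: float,
    z_slice: int,
    meta: dict,
) -> list[ParticleRecord]:
    if not mask2d.any():
        return []
    labels = sk_label(mask2d, connectivity=2)
    records = []
    for rp in regionprops(labels):
        area_px = float(rp.area)
        area = area_px * cal ** 2
        perim = staircase_perimeter(rp.image) * cal
        if area_px >= 2:
            major, minor, angle = fit_ellipse(rp.coords, cal)
        else:  # single pixel: area-equivalent circle
            major = minor = 2.0 * math.sqrt(area / math.pi)
            angle = 0.0
        if minor <= 0:
            minor = major if major > 0 else cal
        circularity = min(1.0, 4.0 * math.pi * area / perim ** 2) if perim > 0 else 1.0
        roundness = min(1.0, 4.0 * area / (math.pi * major ** 2)) if major > 0 else 1.0
        solidity = min(1.0, area_px / float(rp.area_convex))
        records.append(
            ParticleRecord(
                area=area,
                perimeter=perim,
                major_axis=major,
                minor_axis=minor,
                angle=angle,
                aspect_ratio=major / minor,
                circularity=circularity,
                roundness=roundness,
                solidity=solidity,
                z_slice=z_slice,
                **meta,
            )
        )
    return records


def measure_particles(
    mask: BinaryMask,
    calibration: Optional[float] = None,
    subject: str = "",
    group: str = "",
    treatment: str = "",
    fov: int = 0,
) -> list[ParticleRecord]:
    """Shape descriptors for every 8-connected component of a mask.

    Z-stacks are measured slice by slice and the particles pooled (no 3-D
    linking); each record keeps its slice index.
    """
    cal = mask.pixel_size_um if calibration is None else float(calibration)
    if not cal > 0:
        raise ValueError("calibration must be positive")
    meta = dict(subject=subject, group=group, treatment=treatment, fov=fov)
    records: list[ParticleRecord] = []
    for z, sl in enumerate(mask.iter_slices()):
        records.extend(_measure_slice(sl, cal, z, meta))
    return records


def particle_table(records: list[ParticleRecord]) -> pd.DataFrame:
    """Long-format particle table, one row per particle."""
    if not records:
        return pd.DataFrame(
            columns=list(PARAMETER_NAMES) + ["subject", "group", "treatment", "fov", "z_slice"]
        )
    return pd.DataFrame([asdict(r) for r in records])
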