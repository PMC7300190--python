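"""Marker quantification within the mitochondrial area.

Mirrors immunofluorescence quantification of fission/trafficking markers
(DRP1, Rab7A): the mitochondrial area is defined by IsoData thresholding
of the max-projected ATP-synthase channel, and the marker's integrated
intensity inside that area is reported per μm² of mitochondrial surface.
Whole-image fluorescence (Mitotracker-style membrane-potential readouts)
is normalized by an externally supplied cell count or cell surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, CalibratedImage
from .segmentation import binarize_and_clean, max_project, threshold_image

__all__ = ["MarkerQuantRecord", "mito_area_mask", "marker_per_area", "normalized_whole_signal"]


@dataclass
class MarkerQuantRecord:
    sample_id: str
    mito_area_um2: float
    marker_integrated_intensity: float
    marker_per_area: float
    threshold: float
    group: str = ""
    treatment: str = ""


def mito_area_mask(mito: CalibratedImage, min_area_px: int = 0) -> BinaryMask:
    """Mitochondrial area: max projection then IsoData threshold."""
    proj = max_project(mito) if mito.is_stack else mito
    if float(np.ptp(proj.pixels)) == 0:
        raise ValueError("degenerate image: constant intensity, no threshold exists")
    thr = threshold_image(proj, method="isodata")[0]
    mask = binarize_and_clean(proj, thr, min_area_px=min_area_px)
    mask.provenance["threshold_method"] = "isodata"
    mask.provenance["projection"] = "max"
    return mask


def marker_per_area(
    marker: CalibratedImage,
    mask: BinaryMask,
    sample_id: str = "",
    group: str = "",
    treatment: str = "",
) -> MarkerQuantRecord:
    """Integrated marker intensity inside the mask per μm² of mask area."""
    img = max_project(marker) if marker.is_stack else marker
    if img.pixels.shape != mask.pixels.shape:
        raise ValueError("marker image and mask shapes differ")
    area = mask.area_um2
    if area == 0:
        raise ValueError("empty mitochondrial mask")
    integrated = float(img.pixels[mask.pixels].sum())
    return MarkerQuantRecord(
        sample_id=sample_id,
        mito_area_um2=area,
        marker_integrated_intensity=integrated,
        marker_per_area=integrated / area,
        threshold=mask.provenance.get("threshold", float("nan")),
        group=group,
        treatment=treatment,
    )


def normalized_whole_signal(img: CalibratedImage, mode: str, denominator: float) -> float:
    """Whole-image integrated intensity per cell or per μm² of cell surface."""
    if mode not in ("per_cell_count", "per_cell_area"):
        raise ValueError(f"unknown mode {mode!r}")
    if not denominator > 0:
        raise ValueError("denominator must be positive")
    return float(img.pixels.sum()) / float(denominator)
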