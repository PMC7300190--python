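"""Core calibrated-image containers shared by every image operator.

A :class:`CalibratedImage` carries a grayscale 2-D field or a z-stack
(``(z, y, x)``) together with its pixel size in micrometres, so that all
downstream morphometry is reported in physical units.  A
:class:`BinaryMask` is the result of thresholding plus cleanup and keeps
a provenance dictionary (threshold method and value, cleanup
parameters) so every mask is reproducible from its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["CalibratedImage", "BinaryMask"]


@dataclass
class CalibratedImage:
    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2D image or 3D stack, got ndim={self.pixels.ndim}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0] if self.is_stack else 1

    def iter_slices(self):
        """Yield 2-D views (a single yield for a 2-D image)."""
        if self.is_stack:
            yield from self.pixels
        else:
            yield self.pixels

    @property
    def intensity_ceiling(self) -> Optional[float]:
        """Upper bound of the valid intensity range, if one is declared."""
        if self.bit_depth is not None:
            return float(2 ** self.bit_depth - 1)
        if np.issubdtype(self.pixels.dtype, np.integer):
            return float(np.iinfo(self.pixels.dtype).max)
        return None


@dataclass
class BinaryMask:
    pixels: np.ndarray
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            raise ValueError("BinaryMask pixels must be boolean")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("BinaryMask must be 2D or 3D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    def iter_slices(self):
        if self.is_stack:
            yield from self.pixels
        else:
            yield self.pixels

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um ** 2
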