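"""Slide geometry and the fixed-physical-size patch grid.

Whole-slide images are scanned at different resolutions (microns per pixel,
MPP), so a constant *pixel* patch size corresponds to different amounts of
tissue on different slides.  All patching here is therefore specified in
microns: a patch of side ``patch_um`` covers the same physical area on every
slide, and its pixel side length is derived per slide from the MPP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["SlideGeometry", "PatchCoord", "compute_patch_grid", "MissingMPPError"]


class MissingMPPError(ValueError):
    """Raised when a slide has no usable MPP and must be excluded."""


class PatchCoord(NamedTuple):
    """Top-left corner of a patch in slide pixel space.

    Coordinates are 0-based with a top-left origin; the patch covers the
    half-open extent ``[x, x + side_px) x [y, y + side_px)``.
    """

    x: int
    y: int
    side_px: int


@dataclass(frozen=True)
class SlideGeometry:
    """Pixel dimensions and physical resolution of one slide.

    Parameters
    ----------
    width_px, height_px : int
        Slide dimensions in pixels (level 0).
    mpp : float
        Microns per pixel.  Slides with missing or non-positive MPP cannot
        be patched at a constant physical size and must be excluded.
    patch_um : float
        Patch side length in microns.  Default 128 um, i.e. a
        128 x 128 um^2 tissue patch.
    """

    width_px: int
    height_px: int
    mpp: float
    patch_um: float = 128.0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide dimensions must be >= 1 pixel")
        if self.mpp is None or not math.isfinite(self.mpp) or self.mpp <= 0:
            raise MissingMPPError(
                f"MPP is missing or non-positive ({self.mpp!r}); slide must be excluded"
            )
        if not math.isfinite(self.patch_um) or self.patch_um <= 0:
            raise ValueError("patch_um must be positive")
        if self.side_px < 1:
            raise ValueError("patch smaller than one pixel at this MPP")

    @property
    def side_px(self) -> int:
        """Patch side in pixels: round(patch_um / mpp), ties-to-even."""
        return int(round(self.patch_um / self.mpp))

    @property
    def patch_area_mm2(self) -> float:
        """Physical area of one patch in mm^2."""
        return (self.patch_um / 1000.0) ** 2


def compute_patch_grid(geometry: SlideGeometry) -> list[PatchCoord]:
    """Regular non-overlapping patch grid anchored at (0, 0).

    Only patches lying fully inside the slide are kept (partial edge patches
    are discarded), so the grid has ``floor(W/side) * floor(H/side)`` patches,
    in row-major order (y outer, x inner).
    """
    side = geometry.side_px
    nx = geometry.width_px // side
    ny = geometry.height_px // side
    return [
        PatchCoord(ix * side, iy * side, side)
        for iy in range(ny)
        for ix in range(nx)
    ]
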