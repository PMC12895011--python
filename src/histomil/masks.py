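"""Region masks and patch/mask intersection.

A mask marks a tissue region of interest on one slide (e.g. the
pathologist-annotated tumor area).  Canonically it is a set of patch row
indices into the slide's bag; it may instead carry source polygons in slide
pixel space, in which case a patch belongs to the mask when its rectangle
has strictly positive overlap area with any polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .bag import EmbeddingBag

__all__ = ["RegionMask", "patches_intersecting_mask"]


@dataclass
class RegionMask:
    """Tumor (or other) region on one slide.

    Exactly one of ``patch_indices`` (canonical form) or ``polygons`` should
    carry the region; an index mask with no indices is a valid empty mask.
    """

    slide_id: str
    patch_indices: frozenset[int] | None = None
    polygons: tuple[Polygon, ...] | None = None

    def __post_init__(self) -> None:
        if self.patch_indices is None and self.polygons is None:
            raise ValueError("mask needs patch_indices or polygons")
        if self.patch_indices is not None:
            self.patch_indices = frozenset(int(i) for i in self.patch_indices)
            if any(i < 0 for i in self.patch_indices):
                raise ValueError("patch indices must be non-negative")
        if self.polygons is not None:
            self.polygons = tuple(
                p if isinstance(p, Polygon) else Polygon(p) for p in self.polygons
            )


def patches_intersecting_mask(bag: EmbeddingBag, mask: RegionMask) -> frozenset[int]:
    """Row indices of bag patches intersecting the mask.

    Index masks are clipped to the bag's valid range.  For polygonal masks a
    patch counts as intersecting when its half-open pixel rectangle overlaps
    the mask with strictly positive area (touching boundaries do not count).
    """
    if mask.slide_id != bag.slide_id:
        raise ValueError(
            f"mask is for slide {mask.slide_id!r}, bag is slide {bag.slide_id!r}"
        )
    if mask.patch_indices is not None:
        return frozenset(i for i in mask.patch_indices if 0 <= i < bag.n_patches)

    region = shapely.union_all([p for p in mask.polygons])
    side = bag.geometry.side_px
    x, y = bag.coords[:, 0].astype(float), bag.coords[:, 1].astype(float)
    rects = shapely.box(x, y, x + side, y + side)
    overlap = shapely.area(shapely.intersection(rects, region))
    return frozenset(np.flatnonzero(overlap > 0).tolist())
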