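"""Embedding bags: one whole-slide image as a set of patch feature vectors.

Under multiple-instance learning a slide is a *bag* of instances: an N x d
matrix of patch embeddings (one row per tissue patch, produced by a
pretrained encoder) with the pixel coordinate of each patch and the slide's
geometry carried alongside.  The label attaches to the bag, not to patches.

The on-disk container is one HDF5 file per slide with datasets
``features`` (N x d float32) and ``coords`` (N x 2 int64, x then y) and the
attributes ``slide_id``, ``encoder_id``, ``mpp``, ``width_px``,
``height_px``, ``patch_um`` and ``side_px``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .geometry import SlideGeometry

__all__ = ["EmbeddingBag", "read_bag", "write_bag", "export_attention_geojson"]

_REQUIRED_ATTRS = ("slide_id", "encoder_id", "mpp", "width_px", "height_px", "patch_um")


@dataclass
class EmbeddingBag:
    """Patch embeddings of one slide plus aligned coordinates and geometry.

    ``features`` is stored as float32 (the container dtype) and ``coords``
    as an N x 2 int64 array of patch top-left corners, row-aligned with the
    feature matrix.
    """

    slide_id: str
    encoder_id: str
    features: np.ndarray
    coords: np.ndarray
    geometry: SlideGeometry

    def __post_init__(self) -> None:
        self.features = np.ascontiguousarray(self.features, dtype=np.float32)
        self.coords = np.ascontiguousarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty N x d matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must be N x 2 and aligned with features")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("patch coordinates must be unique")
        side = self.geometry.side_px
        x, y = self.coords[:, 0], self.coords[:, 1]
        if (x < 0).any() or (y < 0).any() or (x + side > self.geometry.width_px).any() or (
            y + side > self.geometry.height_px
        ).any():
            raise ValueError("patches must lie fully inside the slide")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "EmbeddingBag":
        """Bag restricted to ``indices`` (original row order preserved)."""
        idx = np.asarray(sorted(set(int(i) for i in np.atleast_1d(indices))), dtype=int)
        if idx.size == 0:
            raise ValueError("cannot build an empty bag")
        if idx.min() < 0 or idx.max() >= self.n_patches:
            raise IndexError("patch index out of range")
        return replace(self, features=self.features[idx], coords=self.coords[idx])


def write_bag(bag: EmbeddingBag, path: str | Path) -> None:
    """Write a bag to its HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features)
        f.create_dataset("coords", data=bag.coords)
        g = bag.geometry
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["encoder_id"] = bag.encoder_id
        f.attrs["mpp"] = g.mpp
        f.attrs["width_px"] = g.width_px
        f.attrs["height_px"] = g.height_px
        f.attrs["patch_um"] = g.patch_um
        f.attrs["side_px"] = g.side_px


def read_bag(path: str | Path) -> EmbeddingBag:
    """Read a bag container, validating the required metadata attributes."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise KeyError(f"bag container {path} lacks required attribute {name!r}")
        geometry = SlideGeometry(
            width_px=int(f.attrs["width_px"]),
            height_px=int(f.attrs["height_px"]),
            mpp=float(f.attrs["mpp"]),
            patch_um=float(f.attrs["patch_um"]),
        )
        return EmbeddingBag(
            slide_id=str(f.attrs["slide_id"]),
            encoder_id=str(f.attrs["encoder_id"]),
            features=f["features"][()],
            coords=f["coords"][()],
            geometry=geometry,
        )


def export_attention_geojson(
    bag: EmbeddingBag, attention: np.ndarray, path: str | Path | None = None
) -> dict:
    """Export per-patch attention as a GeoJSON FeatureCollection.

    Each patch becomes a closed rectangular Polygon in slide pixel
    coordinates with properties ``attention`` (the raw softmax weight) and
    ``attention_rank`` (1 = highest weight; ties broken by patch row order
    so exports are reproducible).  Suitable for overlay in slide viewers
    such as QuPath.
    """
    att = np.asarray(attention, dtype=float)
    if att.shape != (bag.n_patches,):
        raise ValueError(
            f"attention length {att.shape} does not match bag with {bag.n_patches} patches"
        )
    if not np.isclose(att.sum(), 1.0, atol=1e-4):
        raise ValueError("attention weights must sum to 1")

    # stable argsort on -att keeps row order among ties
    order = np.argsort(-att, kind="stable")
    ranks = np.empty(len(att), dtype=int)
    ranks[order] = np.arange(1, len(att) + 1)

    side = bag.geometry.side_px
    features = []
    for i, ((x, y), a, r) in enumerate(zip(bag.coords, att, ranks)):
        x, y = int(x), int(y)
        ring = [[x, y], [x + side, y], [x + side, y + side], [x, y + side], [x, y]]
        features.append(
            {
                "type": "Feature",
                "id": i,
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"attention": float(a), "attention_rank": int(r)},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc
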