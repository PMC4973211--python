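"""File formats and configuration.

Spot centroids come in as CSV (columns ``id,fast_px,slow_px``; extra
columns ignored) — the universal export of any spot finder.  Geometry,
beam and crystal priors are JSON; per-image indexing results go out as
JSON lines with stable key order.  Spots are back-projected onto the Ewald
sphere at load time so an :class:`ImageModel` is always internally
consistent with its geometry and beam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Beam, DetectorGeometry, ObservedSpot, back_project
from .lattice import SpaceGroupInfo, UnitCell

__all__ = [
    "ImageModel",
    "read_spots",
    "write_spots",
    "write_solutions",
    "read_solutions",
    "load_geometry_config",
    "load_crystal_config",
]


@dataclass
class ImageModel:
    """One still image: geometry, beam and its back-projected spot set."""

    image_id: str
    geometry: DetectorGeometry
    beam: Beam
    spots: list[ObservedSpot]

    @classmethod
    def from_pixels(cls, image_id, pixels, geometry: DetectorGeometry,
                    beam: Beam, ids=None) -> "ImageModel":
        pixels = np.asarray(pixels, dtype=float).reshape(-1, 2)
        if ids is None:
            ids = range(len(pixels))
        spots = []
        if len(pixels):
            rlps = back_project(pixels, geometry, beam)
            spots = [
                ObservedSpot(int(i), (float(p[0]), float(p[1])), r)
                for i, p, r in zip(ids, pixels, rlps)
            ]
        return cls(str(image_id), geometry, beam, spots)

    def with_geometry(self, geometry: DetectorGeometry,
                      beam: Beam | None = None) -> "ImageModel":
        """Re-back-project this image's centroids under other geometry."""
        pixels = [s.pixel for s in self.spots]
        ids = [s.id for s in self.spots]
        return ImageModel.from_pixels(self.image_id, pixels, geometry,
                                      beam or self.beam, ids=ids)


_REQUIRED_COLUMNS = ("id", "fast_px", "slow_px")


def read_spots(path, geometry: DetectorGeometry, beam: Beam,
               image_id: str | None = None) -> ImageModel:
    """Load a spot-centroid CSV and back-project onto the Ewald sphere.

    Raises on a missing file, a bad header, or non-numeric/NaN fields (the
    error names the offending rows).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"expected header id,fast_px,slow_px")
    sub = df[list(_REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = (sub.index[bad] + 2).tolist()  # 1-based, counting the header
        raise ValueError(f"{path}: non-numeric or missing values in row(s) {rows}")
    return ImageModel.from_pixels(
        image_id or str(path),
        sub[["fast_px", "slow_px"]].to_numpy(),
        geometry,
        beam,
        ids=sub["id"].astype(int).tolist(),
    )


def write_spots(path, image: ImageModel) -> None:
    """Write an image's centroids back out as id,fast_px,slow_px CSV."""
    df = pd.DataFrame(
        {
            "id": [s.id for s in image.spots],
            "fast_px": [s.pixel[0] for s in image.spots],
            "slow_px": [s.pixel[1] for s in image.spots],
        }
    )
    df.to_csv(path, index=False)


def write_solutions(path, per_image: dict[str, dict]) -> None:
    """JSON lines, one record per image, stable key order.

    Each value must already be a JSON-serialisable mapping, e.g.
    {"image": ..., "n_spots": ..., "solutions": [...]}.
    """
    with open(path, "w") as fh:
        for image_id in per_image:
            rec = per_image[image_id]
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_solutions(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def load_geometry_config(source) -> tuple[DetectorGeometry, Beam]:
    """Geometry + beam from a JSON file path or an already-parsed mapping.

    Expected keys: wavelength_A, bandwidth, distance_mm, beam_centre_px
    [fast, slow], pixel_size_mm, panel_px [n_fast, n_slow].
    """
    cfg = _as_mapping(source)
    geometry = DetectorGeometry(
        distance=float(cfg["distance_mm"]),
        beam_centre=tuple(float(x) for x in cfg["beam_centre_px"]),
        pixel_size=float(cfg["pixel_size_mm"]),
        n_fast=int(cfg["panel_px"][0]),
        n_slow=int(cfg["panel_px"][1]),
    )
    beam = Beam(wavelength=float(cfg["wavelength_A"]),
                bandwidth=float(cfg.get("bandwidth", 0.0)))
    return geometry, beam


def load_crystal_config(source) -> tuple[UnitCell, SpaceGroupInfo]:
    """Crystal prior from JSON: {"cell":[a,b,c,al,be,ga], "spacegroup":"I23"}
    or a generic {"cell":..., "centring":"I", "rotations":[...]} entry."""
    cfg = _as_mapping(source)
    cell = UnitCell(*[float(x) for x in cfg["cell"]])
    return cell, SpaceGroupInfo.from_config(cfg)


def _as_mapping(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return json.load(fh)
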