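"""Detector/beam model and Ewald-sphere back-projection.

Lab frame convention: the incident beam travels along +z with wavevector
``s0 = (0, 0, 1/wavelength)``; the flat detector panel is orthogonal to the
beam at ``z = distance``.  A reciprocal-lattice point (rlp) observed at a
detector pixel is obtained by back-projection onto the nominal Ewald sphere:

    rlp = u / wavelength - s0,

where ``u`` is the unit scattering direction towards the pixel.  With this
convention every recordable rlp has a non-positive z component and satisfies
``|rlp + s0| = |s0|`` exactly, and ``|rlp| = 2 sin(theta) / wavelength``.

Pixel coordinates are 0-based (fast, slow) with pixel centres at integer
coordinates; fractional centroids are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorGeometry",
    "Beam",
    "ObservedSpot",
    "mm_from_pixels",
    "pixels_from_mm",
    "back_project",
    "project_to_detector",
    "ewald_wavelength",
    "NotRecordable",
]


class NotRecordable(ValueError):
    """Raised when a reciprocal point cannot intersect the detector."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat single-panel detector orthogonal to the beam.

    Parameters
    ----------
    distance:
        Crystal-to-detector distance along the beam, mm.
    beam_centre:
        (fast, slow) pixel coordinates where the direct beam hits the panel.
    pixel_size:
        Pixel edge length, mm (square pixels).
    n_fast, n_slow:
        Panel extent in pixels.
    """

    distance: float
    beam_centre: tuple[float, float]
    pixel_size: float
    n_fast: int
    n_slow: int

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError(f"detector distance must be > 0, got {self.distance}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.beam_centre)):
            raise ValueError(f"beam centre must be finite, got {self.beam_centre}")

    def replace_distance(self, distance: float) -> "DetectorGeometry":
        """Same panel at a different crystal-to-detector distance."""
        return DetectorGeometry(distance, self.beam_centre, self.pixel_size,
                                self.n_fast, self.n_slow)


@dataclass(frozen=True)
class Beam:
    """Incident beam: wavelength in Angstrom, fractional bandwidth (full
    width of the wavelength spread, dimensionless)."""

    wavelength: float
    bandwidth: float = 0.0

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.bandwidth < 0:
            raise ValueError(f"bandwidth must be >= 0, got {self.bandwidth}")

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector (0, 0, 1/wavelength), inverse Angstrom."""
        return np.array([0.0, 0.0, 1.0 / self.wavelength])


@dataclass(frozen=True)
class ObservedSpot:
    """A detector centroid together with its back-projected rlp."""

    id: int
    pixel: tuple[float, float]
    rlp: np.ndarray


def mm_from_pixels(pixel, geometry: DetectorGeometry) -> np.ndarray:
    """Detector-plane coordinates in mm relative to the beam centre."""
    pixel = np.asarray(pixel, dtype=float)
    centre = np.asarray(geometry.beam_centre, dtype=float)
    return (pixel - centre) * geometry.pixel_size


def pixels_from_mm(mm, geometry: DetectorGeometry) -> np.ndarray:
    """Inverse of :func:`mm_from_pixels`."""
    mm = np.asarray(mm, dtype=float)
    centre = np.asarray(geometry.beam_centre, dtype=float)
    return mm / geometry.pixel_size + centre


def back_project(pixel, geometry: DetectorGeometry, beam: Beam) -> np.ndarray:
    """Back-project detector pixel(s) onto the nominal Ewald sphere.

    Accepts a single (fast, slow) pair or an (n, 2) array; returns the rlp
     3-vector(s) in inverse Angstrom.
    """
    pixel = np.asarray(pixel, dtype=float)
    single = pixel.ndim == 1
    pixel = np.atleast_2d(pixel)
    xy = mm_from_pixels(pixel, geometry)
    ray = np.concatenate(
        [xy, np.full((len(xy), 1), geometry.distance)], axis=1
    )
    u = ray / np.linalg.norm(ray, axis=1, keepdims=True)
    rlp = u / beam.wavelength - beam.s0
    return rlp[0] if single else rlp


def project_to_detector(
    rlp, geometry: DetectorGeometry, beam: Beam, clip: bool = True
) -> np.ndarray:
    """Project rlp(s) lying on the Ewald sphere to detector pixels.

    The caller is responsible for supplying points near the sphere (rescale
    first if needed); the ray direction is taken as ``rlp + s0``.

    Raises :class:`NotRecordable` for back-scattered points (ray z <= 0) and,
    when ``clip`` is true, for points falling outside the panel.  For array
    input, offending points raise as well — use :func:`project_many` for a
    masked batch version.
    """
    rlp = np.asarray(rlp, dtype=float)
    if rlp.ndim == 1:
        px, ok = project_many(rlp[None, :], geometry, beam, clip=clip)
        if not ok[0]:
            raise NotRecordable("rlp does not intersect the detector panel")
        return px[0]
    px, ok = project_many(rlp, geometry, beam, clip=clip)
    if not ok.all():
        raise NotRecordable(f"{np.count_nonzero(~ok)} rlp(s) not recordable")
    return px


def project_many(rlps, geometry: DetectorGeometry, beam: Beam, clip: bool = True):
    """Vectorised projection: returns (pixels (n,2), recordable mask (n,))."""
    rlps = np.atleast_2d(np.asarray(rlps, dtype=float))
    s = rlps + beam.s0
    sz = s[:, 2]
    ok = sz > 0
    scale = np.where(ok, geometry.distance / np.where(ok, sz, 1.0), np.nan)
    xy_mm = s[:, :2] * scale[:, None]
    px = pixels_from_mm(xy_mm, geometry)
    if clip:
        eps = 1e-6  # tolerate round-trip rounding at the panel edge
        on_panel = (
            (px[:, 0] >= -eps) & (px[:, 0] < geometry.n_fast)
            & (px[:, 1] >= -eps) & (px[:, 1] < geometry.n_slow)
        )
        ok = ok & on_panel
    return px, ok


def ewald_wavelength(rlp) -> float | np.ndarray:
    """Wavelength of the Ewald sphere passing through ``rlp`` and the origin.

    A sphere centred at (0, 0, -1/L) with radius 1/L contains rlp iff
    ``L = -2 rlp_z / |rlp|^2``.  Defined only for rlp_z < 0 (recordable
    half-space); raises for the origin or forward-z points.
    """
    rlp = np.asarray(rlp, dtype=float)
    single = rlp.ndim == 1
    rlp = np.atleast_2d(rlp)
    norm2 = np.einsum("ij,ij->i", rlp, rlp)
    bad = (norm2 <= 0) | (rlp[:, 2] >= 0)
    if bad.any():
        raise ValueError("no Ewald sphere: rlp must be nonzero with negative z")
    lam = -2.0 * rlp[:, 2] / norm2
    return float(lam[0]) if single else lam
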