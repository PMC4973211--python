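"""Pseudo-powder patterns and grid-scan geometry refinement.

A pseudo-powder pattern is a 1-D histogram of inter-spot vector lengths
pooled over a (possibly small) set of still images.  Its peaks sit at the
theoretically allowed inter-reflection distances, so comparing the observed
histogram with the theoretical length table diagnoses errors in detector
distance, wavelength or beam centre: the overlap is sharpest at the true
geometry.  Unlike a conventional (image-sum) powder pattern it also shows
distances whose single reflections are axially absent, because difference
vectors occur off-axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Beam, DetectorGeometry
from .vectors import ToleranceModel, build_spot_vectors, expected_lattices, \
    filter_by_neighbours

__all__ = [
    "PowderPattern",
    "pseudo_powder",
    "theoretical_pattern",
    "powder_fit_score",
    "scan_detector_distance",
    "scan_wavelength",
    "scan_beam_centre",
]

DEFAULT_BIN_WIDTH = 2e-4  # Å⁻¹


@dataclass(frozen=True)
class PowderPattern:
    """Histogram of inter-spot vector lengths pooled over images."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_images: int

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_vectors(self) -> int:
        return int(self.counts.sum())


def _pooled_lengths(images, d_max, filter_lattices=None, tm=None):
    lengths = []
    for img in images:
        sv = build_spot_vectors(img.spots, d_max=d_max)
        if filter_lattices is not None and sv:
            n = expected_lattices(len(img.spots), filter_lattices)
            sv = filter_by_neighbours(sv, n, tm or ToleranceModel(), img.beam)
        lengths.extend(v.length for v in sv)
    return np.asarray(lengths, dtype=float)


def pseudo_powder(
    images,
    d_max: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    spots_per_lattice: float | None = None,
    tolerance_model: ToleranceModel | None = None,
) -> PowderPattern:
    """Pseudo-powder histogram from one or more images.

    ``spots_per_lattice`` switches on the optional neighbour filtering of
    vectors before histogramming (useful on noisy or multi-lattice data).
    """
    images = list(images)
    if not images:
        raise ValueError("at least one image is required")
    lengths = _pooled_lengths(images, d_max, spots_per_lattice, tolerance_model)
    n_bins = max(1, int(np.ceil(d_max / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(lengths, bins=edges)
    return PowderPattern(bin_edges=edges, counts=counts, n_images=len(images))


def theoretical_pattern(theory) -> list[tuple[float, int]]:
    """Distinct theoretical lengths with summed multiplicities."""
    if len(theory) == 0:
        return []
    uniq, counts = theory.unique_lengths()
    return list(zip(uniq.tolist(), counts.tolist()))


def powder_fit_score(
    obs: PowderPattern,
    theory_lengths,
    tol: float = 5e-4,
) -> float:
    """Fraction of observed vectors lying within ``tol`` of a theory length.

    Counts are attributed to their bin centres; higher is better, 1 means
    every observed vector sits on an allowed distance.  Deterministic and
    monotone under improving geometry, which makes it a usable objective
    for the grid scans below.
    """
    total = obs.n_vectors
    if total == 0:
        raise ValueError("no vectors in the observed pattern")
    th = np.sort(np.asarray(
        [t[0] if isinstance(t, (tuple, list)) else t for t in theory_lengths],
        dtype=float))
    if len(th) == 0:
        return 0.0
    centres = obs.bin_centres
    idx = np.searchsorted(th, centres)
    d_lo = np.abs(centres - th[np.clip(idx - 1, 0, len(th) - 1)])
    d_hi = np.abs(th[np.clip(idx, 0, len(th) - 1)] - centres)
    near = np.minimum(d_lo, d_hi) <= tol
    return float(obs.counts[near].sum() / total)


def _rebuilt_images(images, geometry: DetectorGeometry, beam: Beam):
    """Re-back-project every image's pixel centroids under trial geometry."""
    from .io import ImageModel  # local import; io depends on this module's peers

    out = []
    for img in images:
        pixels = np.array([s.pixel for s in img.spots], dtype=float).reshape(-1, 2)
        out.append(ImageModel.from_pixels(img.image_id, pixels, geometry, beam))
    return out


def _grid_scan(images, trials, theory_lengths, d_max, bin_width, tol):
    images = list(images)
    if not trials:
        raise ValueError("scan grid is empty")
    scores = []
    for geometry, beam in trials:
        rebuilt = _rebuilt_images(images, geometry, beam)
        pattern = pseudo_powder(rebuilt, d_max, bin_width)
        if pattern.n_vectors == 0:
            raise ValueError("no vectors: images contribute no inter-spot "
                             "lengths below d_max at the trial geometry")
        scores.append(powder_fit_score(pattern, theory_lengths, tol))
    return np.asarray(scores)


def scan_detector_distance(
    images,
    distance_grid,
    theory_lengths,
    d_max: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 5e-4,
):
    """Best-fitting detector distance over a grid (ties -> smallest).

    Spots are re-back-projected at each trial distance and scored against
    the theoretical length table; returns (best_distance, scores array).
    """
    images = list(images)
    grid = [float(d) for d in distance_grid]
    geom0 = images[0].geometry
    beam0 = images[0].beam
    trials = [(geom0.replace_distance(d), beam0) for d in grid]
    scores = _grid_scan(images, trials, theory_lengths, d_max, bin_width, tol)
    order = np.lexsort((grid, -scores))
    return grid[order[0]], scores


def scan_wavelength(images, wavelength_grid, theory_lengths, d_max,
                    bin_width=DEFAULT_BIN_WIDTH, tol=5e-4):
    """Best-fitting wavelength over a grid (ties -> smallest)."""
    images = list(images)
    grid = [float(w) for w in wavelength_grid]
    geom0 = images[0].geometry
    bw = images[0].beam.bandwidth
    trials = [(geom0, Beam(w, bw)) for w in grid]
    scores = _grid_scan(images, trials, theory_lengths, d_max, bin_width, tol)
    order = np.lexsort((grid, -scores))
    return grid[order[0]], scores


def scan_beam_centre(images, fast_offsets_px, theory_lengths, d_max,
                     bin_width=DEFAULT_BIN_WIDTH, tol=5e-4):
    """Best-fitting beam-centre fast-axis offset over a grid of pixel
    shifts (ties -> smallest offset)."""
    images = list(images)
    grid = [float(o) for o in fast_offsets_px]
    g0 = images[0].geometry
    beam0 = images[0].beam
    trials = []
    for o in grid:
        geom = DetectorGeometry(g0.distance,
                                (g0.beam_centre[0] + o, g0.beam_centre[1]),
                                g0.pixel_size, g0.n_fast, g0.n_slow)
        trials.append((geom, beam0))
    scores = _grid_scan(images, trials, theory_lengths, d_max, bin_width, tol)
    order = np.lexsort((grid, -scores))
    return grid[order[0]], scores
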