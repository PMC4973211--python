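"""Seeded synthetic still-image generator and solution scoring.

The simulator is the exact forward model of :func:`stillindex.acceptance.
predict_spots`: for each lattice a uniformly random orientation U is drawn,
the reflections whose Ewald-sphere radius mismatch fits within the rlp size
plus half the bandwidth are selected and projected to the detector, the
pixel centroids are jittered with isotropic Gaussian noise, and spurious
noise spots are added uniformly in pixel space (mimicking what a spot
finder hands over).  Ground truth (per-lattice orientations, per-spot
labels and Miller indices) is emitted alongside every image.

Intensities, partiality and detector point-spread are deliberately not
modelled: indexing consumes centroid positions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .acceptance import predict_spots
from .geometry import Beam, DetectorGeometry
from .io import ImageModel
from .lattice import SpaceGroupInfo, UnitCell, busing_levy_matrix
from .orientation import pairwise_metric_matrix

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "cpv17_toy_spec",
    "bev_toy_spec",
    "random_orientation",
    "simulate_image",
    "simulate_set",
    "evaluate_solutions",
]

NOISE_LABEL = -1


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one family of synthetic still images."""

    cell: UnitCell
    spacegroup: SpaceGroupInfo
    geometry: DetectorGeometry
    beam: Beam
    rlp_radius: float = 2e-3      # Å⁻¹, effective rlp size (mosaicity etc.)
    jitter_px: float = 0.3        # Gaussian sigma of centroid error, pixels
    noise_fraction: float = 0.1   # spurious spots as a fraction of real ones
    n_lattices: int = 1
    d_max: float = 0.35           # resolution cutoff of simulated spots, Å⁻¹

    def __post_init__(self) -> None:
        if self.n_lattices < 1:
            raise ValueError("n_lattices must be >= 1")
        if self.jitter_px < 0 or self.noise_fraction < 0:
            raise ValueError("jitter and noise fraction must be >= 0")


@dataclass
class GroundTruth:
    """Per-lattice orientations plus per-spot provenance for one image."""

    U: list        # one 3x3 rotation per lattice
    B: np.ndarray
    labels: np.ndarray    # lattice index per spot, NOISE_LABEL for noise
    hkl: np.ndarray       # true Miller indices per spot; zeros for noise

    @property
    def n_lattices(self) -> int:
        return len(self.U)


def cpv17_toy_spec(**overrides) -> SimulationSpec:
    """Cubic I23 toy modelled on the CPV17 setup: a = 106.1 Å, wavelength
    1.46 Å, detector distance 101.2 mm, 0.11 mm pixels on a 1765² panel."""
    base = dict(
        cell=UnitCell(106.1, 106.1, 106.1),
        spacegroup=SpaceGroupInfo.from_symbol("I23"),
        geometry=DetectorGeometry(101.2, (882.0, 882.0), 0.11, 1765, 1765),
        beam=Beam(1.46, 1e-3),
    )
    return SimulationSpec(**{**base, **overrides})


def bev_toy_spec(**overrides) -> SimulationSpec:
    """Large-cell cubic F23 toy modelled on the BEV setup: a = 437 Å,
    wavelength 1.31 Å, detector distance 85 mm (the true value that the
    recorded metadata famously missed by 20 mm)."""
    base = dict(
        cell=UnitCell(437.0, 437.0, 437.0),
        spacegroup=SpaceGroupInfo.from_symbol("F23"),
        geometry=DetectorGeometry(85.0, (882.0, 882.0), 0.11, 1765, 1765),
        beam=Beam(1.31, 1e-3),
        # all Ewald spheres pass through the origin, so at these low
        # scattering angles the sphere-radius mismatch of the selection rule
        # amplifies a geometric rlp size of ~7e-5 Å⁻¹ by ~1/(lambda² q²)
        rlp_radius=0.08,
        d_max=0.05,
    )
    return SimulationSpec(**{**base, **overrides})


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed rotation matrix (quaternion method)."""
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


def image_rng(master_seed: int, image_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one image of a set."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed),
                               spawn_key=(int(image_index),))
    )


def simulate_image(spec: SimulationSpec, rng: np.random.Generator,
                   image_id: str = "sim-0"):
    """One synthetic still image with ground truth.

    Raises if no lattice yields any recordable reflection (the caller may
    redraw with the next stream).
    """
    B = busing_levy_matrix(spec.cell)
    pixels, labels, hkls, Us = [], [], [], []
    for lat in range(spec.n_lattices):
        U = random_orientation(rng)
        Us.append(U)
        H, px, _ = predict_spots(
            U @ B, spec.geometry, spec.beam, spec.rlp_radius, spec.d_max,
            centring=spec.spacegroup.centring,
        )
        pixels.append(px)
        labels.append(np.full(len(px), lat))
        hkls.append(H)
    pixels = np.concatenate(pixels, axis=0)
    labels = np.concatenate(labels)
    hkls = np.concatenate(hkls, axis=0)
    if len(pixels) == 0:
        raise ValueError("simulated image has no recordable reflections")
    if spec.jitter_px > 0:
        pixels = pixels + rng.normal(scale=spec.jitter_px, size=pixels.shape)
    n_noise = int(round(spec.noise_fraction * len(pixels)))
    if n_noise:
        noise = np.column_stack([
            rng.uniform(0, spec.geometry.n_fast, n_noise),
            rng.uniform(0, spec.geometry.n_slow, n_noise),
        ])
        pixels = np.concatenate([pixels, noise], axis=0)
        labels = np.concatenate([labels, np.full(n_noise, NOISE_LABEL)])
        hkls = np.concatenate([hkls, np.zeros((n_noise, 3), dtype=int)], axis=0)
    # clip jittered centroids onto the panel and shuffle deterministically
    pixels[:, 0] = np.clip(pixels[:, 0], 0, spec.geometry.n_fast - 1e-6)
    pixels[:, 1] = np.clip(pixels[:, 1], 0, spec.geometry.n_slow - 1e-6)
    perm = rng.permutation(len(pixels))
    image = ImageModel.from_pixels(image_id, pixels[perm], spec.geometry,
                                   spec.beam)
    truth = GroundTruth(U=Us, B=B, labels=labels[perm], hkl=hkls[perm])
    return image, truth


def simulate_set(spec: SimulationSpec, n_images: int, master_seed: int):
    """A reproducible set of images, each with its own derived stream."""
    images, truths = [], []
    for k in range(n_images):
        rng = image_rng(master_seed, k)
        img, truth = simulate_image(spec, rng, image_id=f"sim-{k}")
        images.append(img)
        truths.append(truth)
    return images, truths


def evaluate_solutions(truth: GroundTruth, found, ops,
                       metric_threshold: float = 0.25) -> dict:
    """Greedy one-to-one matching of found orientations against the truth.

    ``found`` is a list of orientation solutions (or bare U matrices);
    ``ops`` the Cartesian symmetry rotations.  A pair matches when the
    symmetry-aware similarity metric is at most ``metric_threshold``
    (0.25 corresponds to a 10 degree misorientation).  Returns counts of
    matched / missed / spurious lattices and the per-match metrics.
    """
    found_U = [f.U if hasattr(f, "U") else np.asarray(f) for f in found]
    n_t, n_f = len(truth.U), len(found_U)
    report = {"matched": 0, "missed": n_t, "spurious": n_f, "metrics": []}
    if n_t == 0 or n_f == 0:
        return report
    stack = np.array(list(truth.U) + found_U)
    dm = pairwise_metric_matrix(stack, ops)[:n_t, n_t:]
    dm = dm.copy()
    while True:
        k = np.argmin(dm)
        i, j = divmod(int(k), n_f)
        if not dm[i, j] <= metric_threshold:
            break
        report["matched"] += 1
        report["metrics"].append(float(dm[i, j]))
        dm[i, :] = np.inf
        dm[:, j] = np.inf
    report["missed"] = n_t - report["matched"]
    report["spurious"] = n_f - report["matched"]
    return report


def indexing_rate(truths, found_per_image, ops,
                  metric_threshold: float = 0.25) -> dict:
    """Pooled scoring over an image set.

    ``rate`` is lattices correctly recovered per image (the headline
    statistic of serial indexing, which exceeds 1 when multi-lattice images
    are deconvoluted); ``hit_fraction`` is the fraction of images with at
    least one correct lattice.
    """
    matched = missed = spurious = with_hit = 0
    for truth, found in zip(truths, found_per_image):
        rep = evaluate_solutions(truth, found, ops, metric_threshold)
        matched += rep["matched"]
        missed += rep["missed"]
        spurious += rep["spurious"]
        with_hit += bool(rep["matched"])
    n_images = len(truths)
    return {
        "n_images": n_images,
        "matched": matched,
        "missed": missed,
        "spurious": spurious,
        "rate": matched / n_images if n_images else 0.0,
        "hit_fraction": with_hit / n_images if n_images else 0.0,
    }
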