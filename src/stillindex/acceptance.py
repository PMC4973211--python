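"""Solution acceptance statistics and spot prediction.

A correct orientation places the model rlp of every observed spot close to
an Ewald sphere of the nominal wavelength: the spread of per-spot "Ewald
wavelengths" (the wavelength whose sphere passes through the modelled rlp
and the reciprocal origin) is therefore small for a true solution and broad
for a wrong one.  A solution is accepted when that spread falls below a
threshold, or when the wavelength histogram shows a sufficiently high peak.
Spot prediction under an accepted solution also drives multi-lattice
indexing: predicted spots are removed and indexing resumes on the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Beam, DetectorGeometry, ObservedSpot, project_many
from .lattice import centring_allowed

DEFAULT_ASSIGN_TOL = 1.5e-3   # Å⁻¹: spot counted as indexed below this
MIN_CLEAN_COUNT = 5           # smallest clean subset worth trusting
MIN_CLEAN_FRACTION = 0.15     # ... and as a fraction of the spot list

__all__ = [
    "AcceptanceStats",
    "solution_wavelengths",
    "accept_solution",
    "polish_orientation",
    "predict_spots",
    "remove_predicted",
]


@dataclass
class AcceptanceStats:
    """Per-spot Ewald-wavelength statistics for one candidate solution."""

    wavelengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    stdev: float = float("inf")
    peak_height: int = 0
    n_assigned: int = 0

    def to_dict(self) -> dict:
        return {
            "stdev": None if np.isinf(self.stdev) else self.stdev,
            "peak_height": self.peak_height,
            "n_assigned": self.n_assigned,
        }


def _nearest_hkl(R: np.ndarray, rlps: np.ndarray, centring: str):
    """Closest centring-allowed integer hkl for each rlp under R.

    Searches the 3x3x3 integer neighbourhood of round(R^-1 rlp); returns
    (hkl (n,3), model rlps (n,3)).
    """
    Rinv = np.linalg.inv(R)
    frac = rlps @ Rinv.T
    base = np.rint(frac).astype(int)
    offs = np.stack(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    cand = base[:, None, :] + offs[None, :, :]          # (n, 27, 3)
    model = cand @ R.T                                   # (n, 27, 3)
    d2 = np.sum((model - rlps[:, None, :]) ** 2, axis=2)
    ok = centring_allowed(cand.reshape(-1, 3), centring).reshape(d2.shape)
    ok &= np.any(cand != 0, axis=2)
    d2 = np.where(ok, d2, np.inf)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(rlps))
    return cand[rows, best], model[rows, best]


def solution_wavelengths(
    solution,
    spots: list[ObservedSpot],
    geometry: DetectorGeometry,
    beam: Beam,
    d_max: float,
    centring: str = "P",
    assign_tol: float = DEFAULT_ASSIGN_TOL,
) -> AcceptanceStats:
    """Ewald-wavelength spread of a candidate orientation over the spots.

    Each observed rlp (with |rlp| <= d_max) is assigned its nearest allowed
    integer hkl under R; the Ewald wavelength of the modelled rlp R·hkl is
    -2 z / |q|^2.  When enough spots index cleanly (assignment residual at
    most ``assign_tol``) the statistics are restricted to those spots, so
    spurious noise spots and the members of *other* lattices on the image —
    which carry no meaningful index under this orientation — do not drown
    the spread; otherwise all spots contribute, which leaves a wrong
    orientation with its tell-tale broad spread.  The histogram peak uses a
    bin width of wavelength·bandwidth/4 (quarter of the nominal spread).
    """
    R = solution.R if hasattr(solution, "R") else np.asarray(solution)
    rlps = np.array([s.rlp for s in spots], dtype=float).reshape(-1, 3)
    if len(rlps):
        rlps = rlps[np.linalg.norm(rlps, axis=1) <= d_max]
    if len(rlps) == 0:
        return AcceptanceStats()
    _, model = _nearest_hkl(R, rlps, centring)
    resid = np.linalg.norm(model - rlps, axis=1)
    clean = resid <= assign_tol
    norm2 = np.einsum("ij,ij->i", model, model)
    usable = (norm2 > 0) & (model[:, 2] < 0)
    if clean.sum() >= max(MIN_CLEAN_COUNT, MIN_CLEAN_FRACTION * len(rlps)):
        usable &= clean
    lam = -2.0 * model[usable, 2] / norm2[usable]
    if len(lam) == 0:
        return AcceptanceStats()
    bin_width = beam.wavelength * max(beam.bandwidth, 1e-6) / 4.0
    lo = np.floor(lam.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((lam.max() - lo) / bin_width)) + 1)
    counts, _ = np.histogram(lam, bins=n_bins,
                             range=(lo, lo + n_bins * bin_width))
    return AcceptanceStats(
        wavelengths=lam,
        stdev=float(np.std(lam)),
        peak_height=int(counts.max()),
        n_assigned=int(len(lam)),
    )


def polish_orientation(U: np.ndarray, B: np.ndarray,
                       spots: list[ObservedSpot], d_max: float,
                       centring: str = "P", iterations: int = 3,
                       assign_tol: float = DEFAULT_ASSIGN_TOL) -> np.ndarray:
    """Deterministic polish of an orientation against the observed rlps.

    The Ewald-wavelength statistic is so sensitive to misorientation that a
    raw two-vector solution (a few tenths of a degree off on noisy data)
    would fail any useful threshold; each iteration therefore assigns every
    observed rlp its nearest allowed hkl and re-fits U as the least-squares
    rotation (Kabsch) mapping B·hkl onto the observations.  The fit uses the
    cleanly indexing spots (residual at most ``assign_tol``) when there are
    enough of them — noise spots and other lattices must not steer it — and
    falls back to a 3x-median trim otherwise.  This is a minimal alignment
    step, not a full experimental-parameter refinement.
    """
    U = np.asarray(U, dtype=float)
    B = np.asarray(B, dtype=float)
    rlps = np.array([s.rlp for s in spots], dtype=float).reshape(-1, 3)
    if len(rlps):
        rlps = rlps[np.linalg.norm(rlps, axis=1) <= d_max]
    if len(rlps) < 3:
        return U
    for it in range(iterations):
        hkl, model = _nearest_hkl(U @ B, rlps, centring)
        resid = np.linalg.norm(model - rlps, axis=1)
        # first pass tolerates the larger residuals of an unpolished matrix
        tol_it = assign_tol * (2.0 if it == 0 else 1.0)
        keep = resid <= tol_it
        if keep.sum() < max(MIN_CLEAN_COUNT, MIN_CLEAN_FRACTION * len(rlps)):
            keep = resid <= max(3.0 * np.median(resid), 1e-4)
        if keep.sum() < 3:
            break
        T = hkl[keep] @ B.T          # unrotated theoretical positions
        D = rlps[keep]
        M = D.T @ T
        W, _, Vt = np.linalg.svd(M)
        d = np.sign(np.linalg.det(W @ Vt))
        U = W @ np.diag([1.0, 1.0, d]) @ Vt
    return U


def accept_solution(stats: AcceptanceStats, sigma_t: float,
                    min_peak: int, min_assigned: int = 10) -> bool:
    """Accept when the wavelength spread is at most sigma_t (inclusive) or
    the histogram peak reaches min_peak; a solution must assign at least
    ``min_assigned`` spots regardless (a handful of accidentally indexed
    spots can show an arbitrarily tight spread)."""
    if stats.n_assigned < min_assigned:
        return False
    return stats.stdev <= sigma_t or stats.peak_height >= min_peak


def predict_spots(
    solution,
    geometry: DetectorGeometry,
    beam: Beam,
    rlp_radius: float,
    d_max: float,
    centring: str = "P",
):
    """Reflections an orientation predicts on the detector.

    Enumerates centring-allowed hkl with |R·hkl| <= d_max whose Ewald-sphere
    radius mismatch satisfies |1/lambda_i - 1/lambda| <= rlp_radius +
    (bandwidth/2)/lambda, and projects them to pixels.  Returns
    (hkl (n,3) int, pixels (n,2), rlps (n,3)).  This is also the simulator's
    forward model, so simulation and prediction share one selection rule.
    """
    R = solution.R if hasattr(solution, "R") else np.asarray(solution)
    Rinv = np.linalg.inv(R)
    hmax = np.ceil(np.linalg.norm(Rinv, axis=1) * d_max).astype(int)
    axes = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    H = H[centring_allowed(H, centring)]
    q = H @ R.T
    norm2 = np.einsum("ij,ij->i", q, q)
    keep = (norm2 <= d_max**2) & (q[:, 2] < 0)
    H, q, norm2 = H[keep], q[keep], norm2[keep]
    inv_lam_i = norm2 / (-2.0 * q[:, 2])  # Ewald-sphere radius through q
    half_width = rlp_radius + (beam.bandwidth / 2.0) / beam.wavelength
    keep = np.abs(inv_lam_i - 1.0 / beam.wavelength) <= half_width
    H, q = H[keep], q[keep]
    px, ok = project_many(q, geometry, beam) if len(q) else (np.empty((0, 2)),
                                                             np.empty(0, bool))
    return H[ok], px[ok], q[ok]


def remove_predicted(
    spots: list[ObservedSpot],
    predicted_px: np.ndarray,
    radius_px: float = 2.0,
) -> list[ObservedSpot]:
    """Drop spots within radius_px of any predicted pixel position."""
    if radius_px <= 0:
        raise ValueError("removal radius must be > 0")
    predicted_px = np.asarray(predicted_px, dtype=float).reshape(-1, 2)
    if len(predicted_px) == 0 or len(spots) == 0:
        return list(spots)
    px = np.array([s.pixel for s in spots], dtype=float)
    from scipy.spatial import cKDTree

    tree = cKDTree(predicted_px)
    dist, _ = tree.query(px, k=1)
    return [s for s, d in zip(spots, dist) if d > radius_px]
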