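"""Observed inter-spot vectors, length tolerances and theory matching.

An inter-spot vector is the 3-D difference between two back-projected spot
coordinates; when both spots belong to the same lattice it equals a lattice
difference vector, so its length can be matched against the table of
theoretically allowed lengths.  The length tolerance is either a constant
or a resolution-dependent value reflecting the finite rlp size and the
spread of the nest of Ewald spheres across the beam bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Beam, ObservedSpot
from .lattice import TheoreticalVectors

__all__ = [
    "SpotVector",
    "ToleranceModel",
    "build_spot_vectors",
    "length_tolerance",
    "match_to_theory",
    "expected_lattices",
    "filter_by_neighbours",
]

ORIGIN_SPOT_ID = -1  # pseudo-spot at the reciprocal origin, Miller index (0,0,0)


@dataclass
class SpotVector:
    """Observed difference vector between two spots (unordered pair).

    ``matches`` holds indices into a :class:`TheoreticalVectors` table whose
    lengths agree with this vector's within tolerance; populated by
    :func:`match_to_theory`.
    """

    spot_i: int
    spot_j: int
    delta: np.ndarray
    length: float
    matches: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    neighbour_score: int = 0


@dataclass(frozen=True)
class ToleranceModel:
    """Length-tolerance model for vector comparisons.

    mode="fixed": a constant tolerance across the image.
    mode="variable": tol(d) = 2·rlp_radius + d·bandwidth — the two rlp-size
    terms bound the centre displacement of each endpoint, the bandwidth term
    bounds the radial spread between the extreme Ewald spheres of the nest.
    """

    mode: str = "fixed"
    fixed_tol: float = 5e-4
    rlp_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if self.mode == "fixed" and not self.fixed_tol > 0:
            raise ValueError("fixed_tol must be > 0 in fixed mode")
        if self.rlp_radius < 0:
            raise ValueError("rlp_radius must be >= 0")


def length_tolerance(length, tm: ToleranceModel, beam: Beam):
    """Tolerance (Å⁻¹) on a vector of the given length; scalar or array."""
    length = np.asarray(length, dtype=float)
    if tm.mode == "fixed":
        out = np.full_like(length, tm.fixed_tol)
    else:
        out = 2.0 * tm.rlp_radius + length * beam.bandwidth
    return float(out) if out.ndim == 0 else out


def build_spot_vectors(
    spots: list[ObservedSpot],
    d_max: float = np.inf,
    include_origin: bool = False,
) -> list[SpotVector]:
    """All unordered spot pairs with |rlp_j − rlp_i| ≤ d_max.

    With ``include_origin`` every spot is additionally paired with a
    pseudo-spot at the reciprocal origin (the (0,0,0) reflection), which
    boosts the number of usable vectors on sparse images.
    """
    rlps = np.array([s.rlp for s in spots], dtype=float).reshape(-1, 3)
    ids = [s.id for s in spots]
    n = len(spots)
    out: list[SpotVector] = []
    if n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        delta = rlps[jj] - rlps[ii]
        lengths = np.linalg.norm(delta, axis=1)
        keep = (lengths <= d_max) & (lengths > 0)
        for a, b, d, l in zip(ii[keep], jj[keep], delta[keep], lengths[keep]):
            out.append(SpotVector(ids[a], ids[b], d, float(l)))
    if include_origin:
        lengths = np.linalg.norm(rlps, axis=1)
        for k in range(n):
            if 0 < lengths[k] <= d_max:
                out.append(
                    SpotVector(ORIGIN_SPOT_ID, ids[k], rlps[k].copy(),
                               float(lengths[k]))
                )
    return out


def match_to_theory(
    sv: list[SpotVector],
    theory: TheoreticalVectors,
    tm: ToleranceModel,
    beam: Beam,
) -> list[SpotVector]:
    """Populate each vector's theory matches; drop unmatched vectors.

    A theoretical vector matches when the two lengths agree within
    :func:`length_tolerance` of the observed length.  Vectors with no match
    are excluded from the returned indexing pool (the caller may keep the
    original list for pseudo-powder work).
    """
    if len(theory) == 0:
        raise ValueError("theoretical vector table is empty")
    th_len = theory.lengths
    order = np.argsort(th_len, kind="stable")
    sorted_len = th_len[order]
    matched: list[SpotVector] = []
    for v in sv:
        tol = length_tolerance(v.length, tm, beam)
        lo = np.searchsorted(sorted_len, v.length - tol, side="left")
        hi = np.searchsorted(sorted_len, v.length + tol, side="right")
        if hi > lo:
            v.matches = np.sort(order[lo:hi])
            matched.append(v)
    return matched


def expected_lattices(s: int, l: float) -> int:
    """Expected number of lattices on an image: round(s / l), at least 1.

    ``s`` is the spot count, ``l`` the typical spot yield of one lattice.
    Rounding is half-up so the estimate flips lattice count at the midpoint.
    """
    if s < 0:
        raise ValueError("spot count must be >= 0")
    if not l > 0:
        raise ValueError("spots-per-lattice must be > 0")
    return max(1, int(np.floor(s / l + 0.5)))


def filter_by_neighbours(
    sv: list[SpotVector],
    n: int,
    tm: ToleranceModel,
    beam: Beam,
) -> list[SpotVector]:
    """Keep the top 1/n fraction of vectors by neighbour score.

    Two vectors are neighbours when their deltas agree within the length
    tolerance, treating a delta and its negation as the same direction
    (vectors are unordered pairs): min(|da−db|, |da+db|) ≤ tol.  With n
    expected lattices only a fraction p_t = 1/n of vectors is expected to
    be intra-lattice, so a score threshold is chosen such that the retained
    fraction comes as close as possible to p_t; every vector reaching the
    threshold is kept (order-independent — heavily tied scores mean the
    retained fraction can differ from p_t in either direction).
    """
    if n < 1:
        raise ValueError("expected lattice count must be >= 1")
    m = len(sv)
    if m == 0:
        return []
    deltas = np.array([v.delta for v in sv], dtype=float)
    lengths = np.array([v.length for v in sv], dtype=float)
    tol = length_tolerance(lengths, tm, beam)
    tol = np.broadcast_to(np.atleast_1d(tol), (m,))
    scores = np.zeros(m, dtype=int)
    # pairwise in blocks to bound memory on large images
    block = 2048
    for s0 in range(0, m, block):
        sl = slice(s0, min(s0 + block, m))
        d_minus = np.linalg.norm(deltas[sl, None, :] - deltas[None, :, :], axis=2)
        d_plus = np.linalg.norm(deltas[sl, None, :] + deltas[None, :, :], axis=2)
        pair_tol = np.maximum(tol[sl, None], tol[None, :])
        near = np.minimum(d_minus, d_plus) <= pair_tol
        scores[sl] += near.sum(axis=1) - 1  # a vector is not its own neighbour
    for v, sc in zip(sv, scores):
        v.neighbour_score = int(sc)
    if n == 1:
        return list(sv)
    p_t = 1.0 / n
    candidates = np.unique(scores)
    frac = np.array([(scores >= t).sum() / m for t in candidates])
    best = candidates[np.argmin(np.abs(frac - p_t))]  # ties: smaller t wins
    return [v for v in sv if v.neighbour_score >= best]
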