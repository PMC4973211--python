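"""Rotation-matrix algebra for indexing solutions.

An indexing solution is the orientation matrix R = U·B: U is the pure
rotation setting the crystal in the lab frame (the Busing & Levy U matrix)
and B maps integer Miller indices to Cartesian reciprocal coordinates.
U is recovered from a pair of matched inter-spot vectors by two successive
axis-angle rotations, and candidate solutions are compared with a
symmetry-aware matrix-similarity metric (the X-PLOR rotation metric):

    metric(P, Q) = min over symmetry ops O_s of || P - O_s Q ||_F ,

whose value for a pure rotation by angle t relative to the identity is
2·sqrt(2)·sin(t/2); the conventional duplicate threshold of 0.25 thus
corresponds to a misorientation of 10 degrees or less.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrientationSolution",
    "rotation_about_axis",
    "matrix_from_vector_pair",
    "matrices_from_vector_pairs",
    "similarity_metric",
    "pairwise_metric_matrix",
    "angle_threshold_to_metric",
    "polar_projection",
]


@dataclass
class OrientationSolution:
    """A candidate crystal orientation with provenance and statistics.

    ``U`` is orthogonal with determinant +1; ``R = U @ B`` maps integer
    (h, k, l) onto observed reciprocal coordinates.
    """

    U: np.ndarray
    B: np.ndarray
    source: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if not np.allclose(self.U @ self.U.T, np.eye(3), atol=1e-7):
            raise ValueError("U is not orthogonal")
        if np.linalg.det(self.U) < 0:
            raise ValueError("U must be a proper rotation (det +1)")

    @property
    def R(self) -> np.ndarray:
        return self.U @ self.B

    def to_dict(self) -> dict:
        return {
            "U": self.U.tolist(),
            "R": self.R.tolist(),
            "source": self.source,
            "stats": self.stats,
        }


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation by ``angle`` (radians)
    about ``axis`` (need not be unit length).  Rodrigues formula."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _rodrigues_batch(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Batched Rodrigues rotation: axes (n,3) unit, angles (n,) -> (n,3,3)."""
    x, y, z = axes[:, 0], axes[:, 1], axes[:, 2]
    zero = np.zeros_like(x)
    K = np.stack(
        [zero, -z, y, z, zero, -x, -y, x, zero], axis=-1
    ).reshape(-1, 3, 3)
    s = np.sin(angles)[:, None, None]
    c = (1.0 - np.cos(angles))[:, None, None]
    return np.eye(3) + s * K + c * (K @ K)


def _perp_axis(v: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to v: reject the first basis
    vector not parallel to it."""
    for e in np.eye(3):
        p = e - np.dot(e, v) * v / np.dot(v, v)
        if np.linalg.norm(p) > 1e-8:
            return p / np.linalg.norm(p)
    raise ValueError("zero vector has no perpendicular")  # pragma: no cover


def matrices_from_vector_pairs(i_obs, j_obs, i_thr, j_thr) -> np.ndarray:
    """Vectorised orientation recovery for (n,3) stacks of vector pairs.

    Returns U (n,3,3) such that U maps theoretical vectors onto the observed
    directions (U·i_thr parallel to i_obs).  The construction rotates
    observed space onto theoretical space: Q_a takes i_obs onto the
    direction of i_thr about their cross product; Q_b then rotates about
    i_thr by the angle beta that best aligns Q_a·j_obs with j_thr; U is the
    transpose of Q_b·Q_a.  Degenerate pairs are the caller's responsibility
    (use :func:`matrix_from_vector_pair` for checked scalar input).
    """
    i_obs = np.atleast_2d(np.asarray(i_obs, dtype=float))
    j_obs = np.atleast_2d(np.asarray(j_obs, dtype=float))
    i_thr = np.atleast_2d(np.asarray(i_thr, dtype=float))
    j_thr = np.atleast_2d(np.asarray(j_thr, dtype=float))

    io = i_obs / np.linalg.norm(i_obs, axis=1, keepdims=True)
    it = i_thr / np.linalg.norm(i_thr, axis=1, keepdims=True)

    C = np.cross(io, it)
    cn = np.linalg.norm(C, axis=1)
    cosa = np.clip(np.einsum("ij,ij->i", io, it), -1.0, 1.0)
    alpha = np.arctan2(cn, cosa)
    # antiparallel (or parallel) vectors leave the axis undefined; pick a
    # deterministic perpendicular axis instead
    bad = cn < 1e-12
    if bad.any():
        for k in np.flatnonzero(bad):
            C[k] = _perp_axis(io[k])
            cn[k] = 1.0
    Qa = _rodrigues_batch(C / cn[:, None], alpha)

    jp = np.einsum("nij,nj->ni", Qa, j_obs)
    # signed angle between the projections of Qa·j_obs and j_thr onto the
    # plane perpendicular to i_thr, measured about i_thr
    jp_perp = jp - np.einsum("ij,ij->i", jp, it)[:, None] * it
    jt_perp = j_thr - np.einsum("ij,ij->i", j_thr, it)[:, None] * it
    beta = np.arctan2(
        np.einsum("ij,ij->i", it, np.cross(jp_perp, jt_perp)),
        np.einsum("ij,ij->i", jp_perp, jt_perp),
    )
    Qb = _rodrigues_batch(it, beta)
    Qc = Qb @ Qa
    return np.swapaxes(Qc, 1, 2)  # U = Qc^T


def matrix_from_vector_pair(
    i_obs, j_obs, i_thr, j_thr, B: np.ndarray, angle_tol: float = 1e-6
) -> OrientationSolution:
    """Orientation solution from one matched pair of inter-spot vectors.

    ``i_obs``/``j_obs`` are observed-space difference vectors, ``i_thr``/
    ``j_thr`` their assigned theoretical counterparts; all in Å⁻¹.  Raises
    on (anti)parallel i, j pairs — two linearly dependent vectors anchor
    only one axis of reciprocal space.
    """
    i_obs = np.asarray(i_obs, dtype=float)
    j_obs = np.asarray(j_obs, dtype=float)
    i_thr = np.asarray(i_thr, dtype=float)
    j_thr = np.asarray(j_thr, dtype=float)
    for a, b, name in ((i_obs, j_obs, "observed"), (i_thr, j_thr, "theoretical")):
        cross = np.linalg.norm(np.cross(a, b))
        if cross <= angle_tol * np.linalg.norm(a) * np.linalg.norm(b):
            raise ValueError(f"degenerate pair: {name} vectors are parallel")
    U = matrices_from_vector_pairs(i_obs, j_obs, i_thr, j_thr)[0]
    return OrientationSolution(U=U, B=B)


def similarity_metric(P: np.ndarray, Q: np.ndarray, ops) -> float:
    """Symmetry-aware rotation-matrix similarity (X-PLOR metric).

    Minimum over the Cartesian symmetry operators of the Frobenius norm of
    P − Q·O_s.  The operators act in the crystal frame, i.e. on the right
    of an orientation matrix: U and U·O_s index the same lattice.  Zero iff
    P and Q are symmetry-equivalent; for the trivial group it equals
    2√2·sin(misorientation/2).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    best = np.inf
    for O in ops:
        d = np.linalg.norm(P - Q @ O)
        if d < best:
            best = d
    return float(best)


def pairwise_metric_matrix(Us: np.ndarray, ops) -> np.ndarray:
    """All-pairs similarity metric for a stack of rotations (n,3,3).

    Vectorised over pairs and symmetry operators; returns an (n, n)
    symmetric matrix (symmetric because the operator set is a group).
    """
    Us = np.asarray(Us, dtype=float)
    flat = Us.reshape(len(Us), 9)
    best = np.full((len(Us), len(Us)), np.inf)
    for O in ops:
        OQ = (Us @ np.asarray(O)).reshape(len(Us), 9)
        # squared Frobenius distance via the Gram expansion
        d2 = (
            np.einsum("ij,ij->i", flat, flat)[:, None]
            + np.einsum("ij,ij->i", OQ, OQ)[None, :]
            - 2.0 * flat @ OQ.T
        )
        np.minimum(best, d2, out=best)
    return np.sqrt(np.maximum(best, 0.0))


def cross_metric_matrix(A: np.ndarray, B: np.ndarray, ops) -> np.ndarray:
    """Similarity metric between two stacks of rotations: (m,3,3) x (n,3,3)
    -> (m, n), minimised over the symmetry operators."""
    A = np.asarray(A, dtype=float).reshape(-1, 3, 3)
    B = np.asarray(B, dtype=float).reshape(-1, 3, 3)
    Af = A.reshape(len(A), 9)
    best = np.full((len(A), len(B)), np.inf)
    for O in ops:
        Bf = (B @ np.asarray(O)).reshape(len(B), 9)
        d2 = (
            np.einsum("ij,ij->i", Af, Af)[:, None]
            + np.einsum("ij,ij->i", Bf, Bf)[None, :]
            - 2.0 * Af @ Bf.T
        )
        np.minimum(best, d2, out=best)
    return np.sqrt(np.maximum(best, 0.0))


def metric_to_consensus(Us: np.ndarray, consensus: np.ndarray, ops) -> np.ndarray:
    """Similarity metric of each rotation in a stack against one reference."""
    Us = np.asarray(Us, dtype=float).reshape(-1, 3, 3)
    best = np.full(len(Us), np.inf)
    for O in ops:
        d = np.linalg.norm((Us - consensus @ np.asarray(O)).reshape(len(Us), 9),
                           axis=1)
        np.minimum(best, d, out=best)
    return best


def angle_threshold_to_metric(angle_deg: float) -> float:
    """Metric value of a pure rotation by ``angle_deg`` degrees.

    Monotone on [0, 180]; used to express angular radii (e.g. the 8 degree
    neighbourhood, the 10 degree duplicate threshold) in metric units.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    return float(2.0 * np.sqrt(2.0) * np.sin(np.radians(angle_deg) / 2.0))


def polar_projection(R: np.ndarray, reference_axis=(1.0, 0.0, 0.0)):
    """(theta, phi) in degrees of the rotated reference axis.

    ``theta`` is the polar angle from +z, ``phi`` the azimuth in the x-y
    plane; used for the 2-D cluster visualisation of orientation matrices.
    """
    v = np.asarray(R, dtype=float) @ np.asarray(reference_axis, dtype=float)
    v = v / np.linalg.norm(v)
    theta = np.degrees(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(v[1], v[0]))
    return float(theta), float(phi)
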