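"""The two indexing branches: rotation-matrix clusters and vector networks.

Both branches start from observed inter-spot vectors whose lengths match
the theoretical table.  Any two non-parallel matched vectors, together
with an assignment of theoretical counterparts whose mutual angle agrees
with the observed one, determine a candidate orientation.  The cluster
branch builds candidates for every acceptable pair and keeps orientations
surrounded by many neighbours under the symmetry-aware similarity metric;
the network branch grows a self-consistent set of vectors from a seed and
accepts it once it reaches a minimum size.  Multi-lattice indexing removes
the spots predicted by each accepted solution and re-runs on the rest,
rejecting solutions symmetry-equivalent to earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acceptance import (accept_solution, polish_orientation, predict_spots,
                         remove_predicted, solution_wavelengths)
from .io import ImageModel
from .lattice import (SpaceGroupInfo, TheoreticalVectors, UnitCell,
                      busing_levy_matrix, enumerate_theoretical_vectors,
                      lattice_symmetry_ops, rotational_symmetry_ops)
from .orientation import (OrientationSolution, angle_threshold_to_metric,
                          cross_metric_matrix, matrices_from_vector_pairs,
                          metric_to_consensus, pairwise_metric_matrix)
from .vectors import (ToleranceModel, build_spot_vectors, expected_lattices,
                      filter_by_neighbours, match_to_theory)

__all__ = [
    "IndexingParams",
    "CrystalPriors",
    "VectorNetwork",
    "candidate_pairs",
    "cluster_index",
    "grow_network",
    "network_index",
    "index_image",
    "multi_cycle",
]


@dataclass(frozen=True)
class IndexingParams:
    """Tunable knobs of the indexing pipeline.

    Angular quantities are degrees; reciprocal lengths are inverse
    Angstrom.  ``d_max`` bounds the inter-spot vectors used for indexing,
    ``spot_d_max`` the resolution range of spots considered for prediction
    and acceptance statistics.
    """

    method: str = "network"
    d_max: float = 0.10
    tolerance: ToleranceModel = field(default_factory=ToleranceModel)
    pair_angle_tol: float = 1.0
    neighbour_radius: float = 8.0
    network_threshold: int = 20
    require_common_spot: bool = True
    max_lattices: int = 1
    duplicate_metric_threshold: float = 0.25
    include_origin: bool = True
    filter_spots_per_lattice: float | None = None
    # acceptance stage
    sigma_t: float = 0.02
    min_peak: int = 10
    spot_d_max: float = 0.35
    rlp_radius: float = 2e-3
    removal_radius_px: float = 2.0
    # deterministic resource caps
    max_candidate_vectors: int = 80
    max_candidates: int = 3000
    max_seeds: int = 40
    max_bootstrap: int = 4
    boot_samples: int = 24
    max_combos: int = 6000
    consistency_checks: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("network", "cluster"):
            raise ValueError(f"unknown indexing method {self.method!r}")
        if not 0.0 < self.duplicate_metric_threshold < 2.0 * np.sqrt(2.0):
            raise ValueError("duplicate threshold must lie in (0, 2*sqrt(2))")
        for name in ("d_max", "pair_angle_tol", "neighbour_radius",
                     "network_threshold", "max_lattices"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def neighbour_metric_radius(self) -> float:
        return angle_threshold_to_metric(self.neighbour_radius)


@dataclass(frozen=True)
class CrystalPriors:
    """Unit cell + space group with the derived quantities indexing needs."""

    cell: UnitCell
    spacegroup: SpaceGroupInfo
    B: np.ndarray
    theory: TheoreticalVectors
    ops: tuple          # Cartesian crystal point-group rotations
    lattice_ops: tuple  # proper rotations of the Bravais lattice (these can
                        # exceed the crystal's: geometric equivalence)

    @classmethod
    def build(cls, cell: UnitCell, spacegroup: SpaceGroupInfo,
              d_max: float) -> "CrystalPriors":
        B = busing_levy_matrix(cell)
        theory = enumerate_theoretical_vectors(cell, spacegroup, d_max)
        ops = tuple(rotational_symmetry_ops(spacegroup, B))
        try:
            lat = tuple(lattice_symmetry_ops(cell, spacegroup.centring, B))
        except Exception:
            lat = ops
        return cls(cell, spacegroup, B, theory, ops, lat)


@dataclass
class VectorNetwork:
    """A self-consistent set of matched vectors for one indexing solution."""

    members: list          # (vector index in pool, theory index) pairs
    spot_ids: set
    consensus: OrientationSolution

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# candidate enumeration (shared by the cluster branch and its oracle test)

def candidate_pairs(matched, theory: TheoreticalVectors,
                    pair_angle_tol: float = 1.0,
                    max_candidates: int | None = None):
    """All (vector pair, theory assignment) candidates for a solution.

    A pair of matched vectors is a candidate when the observed angle
    between them matches the angle between some assignment of their
    theoretical counterparts within ``pair_angle_tol`` degrees.  Pairs
    closer than the tolerance to parallel or antiparallel are excluded
    (they anchor only one axis).  Returns tuples (i, j, theory_i,
    theory_j) in deterministic order, truncated at ``max_candidates``.
    """
    tol = pair_angle_tol
    th_unit = theory.cart / theory.lengths[:, None]
    deltas = np.array([v.delta for v in matched], dtype=float).reshape(-1, 3)
    if len(deltas):
        units = deltas / np.linalg.norm(deltas, axis=1, keepdims=True)
    out = []
    for a in range(len(matched)):
        for b in range(a + 1, len(matched)):
            cos_obs = float(np.clip(np.dot(units[a], units[b]), -1.0, 1.0))
            ang_obs = np.degrees(np.arccos(cos_obs))
            if ang_obs < tol or ang_obs > 180.0 - tol:
                continue
            Ta = th_unit[matched[a].matches]
            Tb = th_unit[matched[b].matches]
            ang_thr = np.degrees(np.arccos(np.clip(Ta @ Tb.T, -1.0, 1.0)))
            good = np.argwhere(np.abs(ang_thr - ang_obs) <= tol)
            for i, j in good:
                out.append((a, b, int(matched[a].matches[i]),
                            int(matched[b].matches[j])))
                if max_candidates is not None and len(out) >= max_candidates:
                    return out
    return out


def _accept_stage(solution, spots, image: ImageModel, params: IndexingParams,
                  priors: CrystalPriors):
    """Polish the candidate orientation, attach its wavelength-spread
    statistics and apply the acceptance thresholds (mutates solution)."""
    solution.U = polish_orientation(solution.U, priors.B, spots,
                                    params.spot_d_max,
                                    centring=priors.spacegroup.centring)
    stats = solution_wavelengths(solution, spots, image.geometry, image.beam,
                                 params.spot_d_max,
                                 centring=priors.spacegroup.centring)
    solution.stats.update(stats.to_dict())
    return accept_solution(stats, params.sigma_t, params.min_peak)


def _is_duplicate(U, accepted, ops, threshold):
    for sol in accepted:
        if metric_to_consensus(U[None], sol.U, ops)[0] < threshold:
            return True
    return False


def _matched_pool(spots, params: IndexingParams, priors: CrystalPriors, beam):
    sv = build_spot_vectors(spots, d_max=params.d_max,
                            include_origin=params.include_origin)
    matched = match_to_theory(sv, priors.theory, params.tolerance, beam)
    if params.filter_spots_per_lattice is not None and matched:
        n = expected_lattices(len(spots), params.filter_spots_per_lattice)
        matched = filter_by_neighbours(matched, n, params.tolerance, beam)
    return matched


# ---------------------------------------------------------------------------
# first branch: rotation-matrix clusters

def cluster_index(image: ImageModel, params: IndexingParams,
                  priors: CrystalPriors):
    """Indexing by clustering candidate orientation matrices.

    Builds an orientation for every candidate pair/assignment, counts
    neighbours within the angular radius under the similarity metric, and
    greedily selects the most-surrounded orientations, dropping symmetry
    duplicates and solutions failing the acceptance stage.
    """
    matched = _matched_pool(image.spots, params, priors, image.beam)
    if len(matched) > params.max_candidate_vectors:
        order = sorted(range(len(matched)),
                       key=lambda k: (len(matched[k].matches),
                                      -matched[k].length))
        matched = [matched[k] for k in order[:params.max_candidate_vectors]]
    cands = candidate_pairs(matched, priors.theory, params.pair_angle_tol,
                            params.max_candidates)
    if not cands:
        return []
    i_obs = np.array([matched[a].delta for a, _, _, _ in cands])
    j_obs = np.array([matched[b].delta for _, b, _, _ in cands])
    i_thr = priors.theory.cart[[ti for _, _, ti, _ in cands]]
    j_thr = priors.theory.cart[[tj for _, _, _, tj in cands]]
    Us = matrices_from_vector_pairs(i_obs, j_obs, i_thr, j_thr)
    dm = pairwise_metric_matrix(Us, priors.ops)
    neighbours = (dm <= params.neighbour_metric_radius).sum(axis=1) - 1
    order = np.lexsort((np.arange(len(cands)), -neighbours))
    accepted: list[OrientationSolution] = []
    for k in order:
        if len(accepted) >= params.max_lattices:
            break
        U = Us[k]
        if _is_duplicate(U, accepted, priors.lattice_ops,
                         params.duplicate_metric_threshold):
            continue
        a, b, ti, tj = cands[k]
        sol = OrientationSolution(
            U=U, B=priors.B,
            source={"kind": "cluster", "pair": (a, b), "theory": (ti, tj)},
            stats={"neighbours": int(neighbours[k])},
        )
        if not _accept_stage(sol, image.spots, image, params, priors):
            continue
        accepted.append(sol)
    return accepted


# ---------------------------------------------------------------------------
# second branch: inter-spot vector networks

def _flatten_matches(matched, theory):
    """Parallel arrays over every (vector, theory match) combination."""
    vec_idx, th_idx = [], []
    for k, v in enumerate(matched):
        vec_idx.extend([k] * len(v.matches))
        th_idx.extend(v.matches.tolist())
    vec_idx = np.asarray(vec_idx, dtype=int)
    th_idx = np.asarray(th_idx, dtype=int)
    return vec_idx, th_idx


def grow_network(seed: int, matched, params: IndexingParams,
                 priors: CrystalPriors) -> VectorNetwork | None:
    """Grow a self-consistent vector network from a seed vector.

    Each theory assignment of the seed defines a family of bootstrap
    pairings with other pool vectors (angle pre-screened, deterministic
    order).  Within a family, every pairing's orientation is scored by its
    support — the number of pool vectors whose own pairing with the seed
    lies within the neighbour radius of it — and the best-supported
    orientation becomes the trial consensus.  Admissible vectors are then
    admitted in deterministic passes, honouring the common-spot
    requirement and the member-consistency checks.  The first consensus
    whose network reaches ``network_threshold`` wins; returns None when
    none does ("too small").
    """
    theory = priors.theory
    tol = params.pair_angle_tol
    radius = params.neighbour_metric_radius
    size_cap = max(params.network_threshold + 10, 30)

    deltas = np.array([v.delta for v in matched], dtype=float).reshape(-1, 3)
    units = deltas / np.linalg.norm(deltas, axis=1, keepdims=True)
    th_unit = theory.cart / theory.lengths[:, None]
    vec_idx, th_idx = _flatten_matches(matched, theory)

    seed_v = matched[seed]
    cos_obs = np.clip(units @ units[seed], -1.0, 1.0)
    ang_obs = np.degrees(np.arccos(cos_obs))           # per pool vector

    for ti in seed_v.matches[: params.max_bootstrap]:
        # angle screen of every (vector, match) combo against (seed, ti)
        ang_thr = np.degrees(np.arccos(np.clip(
            th_unit[th_idx] @ th_unit[ti], -1.0, 1.0)))
        ok = (np.abs(ang_thr - ang_obs[vec_idx]) <= tol) \
            & (ang_obs[vec_idx] >= tol) & (ang_obs[vec_idx] <= 180.0 - tol) \
            & (vec_idx != seed)
        cand_v = vec_idx[ok]
        cand_t = th_idx[ok]
        if len(cand_v) + 1 < params.network_threshold:
            continue
        if len(cand_v) > params.max_combos:
            cand_v = cand_v[: params.max_combos]
            cand_t = cand_t[: params.max_combos]
        Us = matrices_from_vector_pairs(
            np.broadcast_to(seed_v.delta, (len(cand_v), 3)),
            deltas[cand_v],
            np.broadcast_to(theory.cart[ti], (len(cand_v), 3)),
            theory.cart[cand_t],
        )
        # sample bootstrap consensus candidates across distinct vectors and
        # score each by support: how many vectors admit it
        first_of_vec = np.flatnonzero(np.concatenate(
            [[True], cand_v[1:] != cand_v[:-1]]))
        stride = max(1, len(first_of_vec) // params.boot_samples)
        boots = first_of_vec[::stride][: params.boot_samples]
        C = cross_metric_matrix(Us[boots], Us, priors.ops)
        support = np.array([
            len(np.unique(cand_v[C[b] <= radius])) for b in range(len(boots))
        ])
        order = np.lexsort((boots, -support))
        for b in order[:2]:  # best-supported consensus (plus one fallback)
            if support[b] + 1 < params.network_threshold:
                break
            consensus_U = Us[boots[b]]
            m = C[b]
            # one admissible assignment per vector: smallest metric wins
            best: dict[int, tuple[float, int, int]] = {}
            for k in np.flatnonzero(m <= radius):
                v = int(cand_v[k])
                if v not in best or m[k] < best[v][0]:
                    best[v] = (float(m[k]), int(cand_t[k]), int(k))
            net = _assemble_network(seed, int(ti), best, matched, Us,
                                    consensus_U, params, priors, size_cap)
            if net is not None:
                return net
    return None


def _assemble_network(seed, seed_t, best, matched, Us, consensus_U,
                      params: IndexingParams, priors: CrystalPriors,
                      size_cap: int) -> VectorNetwork | None:
    """Admit admissible vectors in passes, honouring common-spot linkage."""
    members = [(seed, seed_t)]
    spot_ids = {matched[seed].spot_i, matched[seed].spot_j}
    pending = sorted(best.items())  # by vector index: deterministic
    changed = True
    while changed and len(members) < size_cap:
        changed = False
        remaining = []
        for v, (metric, t, k) in pending:
            if len(members) >= size_cap:
                break
            vec = matched[v]
            if params.require_common_spot and not (
                vec.spot_i in spot_ids or vec.spot_j in spot_ids
            ):
                remaining.append((v, (metric, t, k)))
                continue
            if not _member_consistent(v, t, members, matched, consensus_U,
                                      params, priors):
                # re-examined on later passes: the member subset changes
                remaining.append((v, (metric, t, k)))
                continue
            members.append((v, t))
            spot_ids.update((vec.spot_i, vec.spot_j))
            changed = True
        pending = remaining
    if len(members) < params.network_threshold:
        return None
    consensus = OrientationSolution(
        U=consensus_U, B=priors.B,
        source={"kind": "network", "seed": seed, "size": len(members)},
        stats={"network_size": len(members)},
    )
    return VectorNetwork(members=members, spot_ids=spot_ids,
                         consensus=consensus)


def _member_consistent(v, t, members, matched, consensus_U,
                       params: IndexingParams, priors: CrystalPriors) -> bool:
    """Pair the candidate with a bounded member subset; all pair matrices
    must fall within the neighbour radius of the consensus."""
    theory = priors.theory
    n_check = min(params.consistency_checks, len(members))
    if n_check <= 1:
        subset = members[:1]
    else:
        # first member, plus evenly spaced recent ones
        step = max(1, len(members) // (n_check - 1))
        subset = [members[0]] + members[1::step][: n_check - 1]
    cand = matched[v]
    checks_i, checks_j, thr_i, thr_j = [], [], [], []
    for mv, mt in subset:
        a = matched[mv].delta
        b = cand.delta
        cross = np.linalg.norm(np.cross(a, b))
        if cross <= 1e-12:
            continue  # parallel member: no constraint from this pairing
        checks_i.append(a)
        checks_j.append(b)
        thr_i.append(theory.cart[mt])
        thr_j.append(theory.cart[t])
    if not checks_i:
        return False
    Us = matrices_from_vector_pairs(np.array(checks_i), np.array(checks_j),
                                    np.array(thr_i), np.array(thr_j))
    m = metric_to_consensus(Us, consensus_U, priors.ops)
    return bool(np.all(m <= params.neighbour_metric_radius))


def network_index(image: ImageModel, params: IndexingParams,
                  priors: CrystalPriors):
    """Network-branch indexing with multi-lattice iteration.

    Seeds are tried most-specific-first (fewest theory matches, then
    longest — long vectors carry proportionately lower error).  After a
    network passes the acceptance stage its predicted spots are removed
    and indexing resumes on the remainder, up to ``max_lattices``;
    solutions symmetry-equivalent to an earlier one are rejected.
    """
    spots = list(image.spots)
    accepted: list[OrientationSolution] = []
    for _ in range(params.max_lattices):
        if len(spots) < 3:
            break
        matched = _matched_pool(spots, params, priors, image.beam)
        if len(matched) < params.network_threshold:
            break
        seed_order = sorted(range(len(matched)),
                            key=lambda k: (len(matched[k].matches),
                                           -matched[k].length))
        found = None
        for seed in seed_order[: params.max_seeds]:
            net = grow_network(seed, matched, params, priors)
            if net is None:
                continue
            sol = net.consensus
            if _is_duplicate(sol.U, accepted, priors.lattice_ops,
                             params.duplicate_metric_threshold):
                continue
            if not _accept_stage(sol, spots, image, params, priors):
                continue
            found = sol
            break
        if found is None:
            break
        accepted.append(found)
        _, pred_px, _ = predict_spots(found.R, image.geometry, image.beam,
                                      params.rlp_radius, params.spot_d_max,
                                      centring=priors.spacegroup.centring)
        spots = remove_predicted(spots, pred_px, params.removal_radius_px)
    return accepted


def index_image(image: ImageModel, params: IndexingParams,
                priors: CrystalPriors):
    """Dispatch to the configured branch."""
    if params.method == "cluster":
        return cluster_index(image, params, priors)
    return network_index(image, params, priors)


def multi_cycle(images, schedule, priors: CrystalPriors):
    """Run a parameter schedule: each cycle attempts only the images left
    unindexed by earlier cycles (tightening tolerances / relaxing the
    network threshold across cycles, as one would on hard data).

    Returns (per-image solution lists, cumulative indexed fraction per
    cycle).
    """
    if not schedule:
        raise ValueError("schedule must contain at least one cycle")
    images = list(images)
    solutions: list[list] = [[] for _ in images]
    cumulative = []
    for params in schedule:
        for k, image in enumerate(images):
            if solutions[k]:
                continue
            solutions[k] = index_image(image, params, priors)
        indexed = sum(bool(s) for s in solutions)
        cumulative.append(indexed / len(images) if images else 0.0)
    return solutions, cumulative
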