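"""Unit cell, space-group symmetry and theoretical inter-reflection vectors.

The unit-cell transformation matrix is the Busing & Levy (1967) **B** matrix
in its upper-triangular convention: it maps integer Miller indices (h, k, l)
to Cartesian reciprocal coordinates in inverse Angstrom.  "Theoretical
space" is the set of difference vectors between reflections allowed by the
lattice centring — centring absences forbid whole classes of inter-spot
difference vectors, whereas axial (screw-axis) absences only remove
individual reflections and never a general difference, so they are not
applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SpaceGroupInfo",
    "TheoreticalVectors",
    "busing_levy_matrix",
    "centring_allowed",
    "enumerate_theoretical_vectors",
    "rotational_symmetry_ops",
    "lattice_symmetry_ops",
    "collate_lengths",
]


@dataclass(frozen=True)
class UnitCell:
    """Direct unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in self.angles)
        arg = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
        if arg <= 0:
            raise ValueError(f"degenerate unit cell {self}")
        return self.a * self.b * self.c * float(np.sqrt(arg))


def busing_levy_matrix(cell: UnitCell) -> np.ndarray:
    """Upper-triangular B matrix mapping (h,k,l) to Cartesian Å⁻¹.

    Columns are the reciprocal basis vectors a*, b*, c* expressed with a*
    along x and b* in the x-y plane; the third diagonal entry is 1/c.
    """
    cell.volume()  # raises on degenerate input
    g = gemmi.UnitCell(*cell.lengths, *cell.angles)
    rec = g.reciprocal()
    a_s, b_s, c_s = rec.a, rec.b, rec.c
    cos_bs = np.cos(np.radians(rec.beta))
    cos_gs = np.cos(np.radians(rec.gamma))
    sin_bs = np.sin(np.radians(rec.beta))
    sin_gs = np.sin(np.radians(rec.gamma))
    cos_al = np.cos(np.radians(cell.alpha))
    return np.array(
        [
            [a_s, b_s * cos_gs, c_s * cos_bs],
            [0.0, b_s * sin_gs, -c_s * sin_bs * cos_al],
            [0.0, 0.0, 1.0 / cell.c],
        ]
    )


_CENTRING_RULES = {
    "P": lambda h, k, l: np.ones_like(h, dtype=bool),
    "I": lambda h, k, l: (h + k + l) % 2 == 0,
    "F": lambda h, k, l: ((h % 2 == k % 2) & (k % 2 == l % 2)),
    "C": lambda h, k, l: (h + k) % 2 == 0,
    "A": lambda h, k, l: (k + l) % 2 == 0,
    "B": lambda h, k, l: (h + l) % 2 == 0,
    "R": lambda h, k, l: (-h + k + l) % 3 == 0,  # obverse setting
}


def centring_allowed(hkl, centring: str):
    """Whether reflection indices survive the lattice-centring condition.

    Accepts one (h,k,l) or an (n,3) array; returns bool or bool array.
    """
    try:
        rule = _CENTRING_RULES[centring]
    except KeyError:
        raise ValueError(f"unknown centring symbol {centring!r}") from None
    hkl = np.asarray(hkl, dtype=int)
    single = hkl.ndim == 1
    hkl = np.atleast_2d(hkl)
    out = rule(hkl[:, 0], hkl[:, 1], hkl[:, 2])
    return bool(out[0]) if single else out


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Centring type plus the proper rotational parts of the point group.

    ``rotations`` are integer matrices acting on Miller indices in the
    crystal (fractional) frame; they form a group containing the identity.
    """

    symbol: str
    centring: str
    rotations: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.centring not in _CENTRING_RULES:
            raise ValueError(f"unknown centring symbol {self.centring!r}")
        rots = tuple(np.asarray(r, dtype=int) for r in self.rotations)
        if not rots:
            rots = (np.eye(3, dtype=int),)
        object.__setattr__(self, "rotations", rots)
        key = {m.tobytes() for m in rots}
        if np.eye(3, dtype=int).tobytes() not in key:
            raise ValueError("rotation set must contain the identity")
        for p in rots:
            for q in rots:
                if (p @ q).tobytes() not in key:
                    raise ValueError("rotation set is not closed under product")

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupInfo":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unsupported space-group symbol {symbol!r}")
        seen: dict[bytes, np.ndarray] = {}
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
            roti = np.rint(rot).astype(int)
            if not np.allclose(rot, roti):
                continue  # non-crystallographic fraction; cannot occur for rot parts
            if round(np.linalg.det(roti)) != 1:
                continue  # keep proper rotations only
            seen.setdefault(roti.tobytes(), roti)
        return cls(symbol=sg.hm.replace(" ", ""),
                   centring=sg.centring_type(),
                   rotations=tuple(seen.values()))

    @classmethod
    def from_config(cls, spec: dict) -> "SpaceGroupInfo":
        """Build from a config mapping: either {"spacegroup": "I23"} or a
        generic {"centring": "I", "rotations": [[[...]]...]} entry."""
        if "spacegroup" in spec:
            return cls.from_symbol(spec["spacegroup"])
        rots = tuple(np.asarray(r, dtype=int) for r in spec.get("rotations", []))
        return cls(symbol=spec.get("symbol", spec["centring"]),
                   centring=spec["centring"], rotations=rots)


def lattice_symmetry_ops(cell: UnitCell, centring: str, B: np.ndarray,
                         max_obliq: float = 1.5) -> list[np.ndarray]:
    """Proper rotations of the Bravais lattice, Cartesian reciprocal frame.

    The lattice's point symmetry can exceed the crystal's (e.g. a cubic
    I-centred lattice has 432 symmetry while the crystal class may be 23).
    Orientations related by a lattice — but not crystal — rotation predict
    identical spot positions and are geometrically equivalent for indexing
    (the merohedral indexing ambiguity); use these operators to recognise
    geometrically equivalent solutions.
    """
    g = gemmi.find_lattice_symmetry(
        gemmi.UnitCell(*cell.lengths, *cell.angles), centring, max_obliq)
    seen: dict[bytes, np.ndarray] = {}
    for op in g.sym_ops:
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        roti = np.rint(rot).astype(int)
        if not np.allclose(rot, roti) or round(np.linalg.det(roti)) != 1:
            continue
        seen.setdefault(roti.tobytes(), roti)
    sg = SpaceGroupInfo(symbol=f"lattice({centring})", centring=centring,
                        rotations=tuple(seen.values()))
    return rotational_symmetry_ops(sg, B)


def rotational_symmetry_ops(sg: SpaceGroupInfo, B: np.ndarray) -> list[np.ndarray]:
    """Point-group rotations expressed in the Cartesian reciprocal frame.

    A fractional rotation W acting on real space moves Miller indices by
    W⁻ᵀ; conjugation by B carries that action onto Cartesian reciprocal
    coordinates.  For genuine lattice symmetries the result is orthogonal.
    """
    Binv = np.linalg.inv(B)
    ops = []
    for W in sg.rotations:
        M = B @ np.linalg.inv(W).T @ Binv
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise ValueError(
                f"operator {W.tolist()} is not a symmetry of this cell"
            )
        ops.append(M)
    return ops


class TheoreticalVectors:
    """Allowed inter-reflection difference vectors below a length cutoff.

    Stored as parallel arrays: integer index differences ``dhkl`` (n, 3),
    Cartesian vectors ``cart`` (n, 3) in Å⁻¹ and their ``lengths`` (n,).
    Both a difference and its negation are kept; downstream matching treats
    them as distinct candidates.
    """

    def __init__(self, dhkl: np.ndarray, cart: np.ndarray) -> None:
        self.dhkl = np.asarray(dhkl, dtype=int).reshape(-1, 3)
        self.cart = np.asarray(cart, dtype=float).reshape(-1, 3)
        self.lengths = np.linalg.norm(self.cart, axis=1)
        order = np.lexsort((self.dhkl[:, 2], self.dhkl[:, 1],
                            self.dhkl[:, 0], self.lengths))
        self.dhkl = self.dhkl[order]
        self.cart = self.cart[order]
        self.lengths = self.lengths[order]

    def __len__(self) -> int:
        return len(self.lengths)

    def unique_lengths(self, bin_tol: float = 1e-6):
        """Distinct lengths with multiplicities (counts of index pairs),
        collating values closer than ``bin_tol``."""
        return collate_lengths(self.lengths, bin_tol)


def collate_lengths(lengths: np.ndarray, bin_tol: float = 1e-6):
    """Collate a sorted-or-not length array into (unique lengths, counts)."""
    lengths = np.sort(np.asarray(lengths, dtype=float))
    if len(lengths) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    breaks = np.flatnonzero(np.diff(lengths) > bin_tol)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(lengths)]])
    uniq = np.array([lengths[s:e].mean() for s, e in zip(starts, ends)])
    counts = ends - starts
    return uniq, counts


def enumerate_theoretical_vectors(
    cell: UnitCell,
    sg: SpaceGroupInfo,
    d_max: float,
    include_origin: bool = False,
    max_vectors: int = 2_000_000,
) -> TheoreticalVectors:
    """All centring-allowed integer difference vectors with |B·dhkl| ≤ d_max.

    Axial systematic absences are deliberately not applied: a screw axis
    forbids individual axial reflections but the corresponding difference
    still occurs between general reflection pairs.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    B = busing_levy_matrix(cell)
    Binv = np.linalg.inv(B)
    # |h_i| = |row_i(B⁻¹)·q| ≤ ||row_i(B⁻¹)||·d_max bounds the index search box
    hmax = np.ceil(np.linalg.norm(Binv, axis=1) * d_max).astype(int)
    n_grid = np.prod(2 * hmax + 1)
    if n_grid > max_vectors:
        raise ValueError(
            f"theoretical-vector grid of {n_grid} candidates exceeds the cap "
            f"of {max_vectors}; reduce d_max or raise max_vectors"
        )
    axes = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    cart = H @ B.T
    keep = np.einsum("ij,ij->i", cart, cart) <= d_max**2
    keep &= centring_allowed(H, sg.centring)
    if not include_origin:
        keep &= np.any(H != 0, axis=1)
    return TheoreticalVectors(H[keep], cart[keep])
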