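"""The 27-letter protein folding shape code (PFSC) for Cα fragments.

A *folden* — five consecutive amino-acid residues — is the smallest
backbone unit that shows how a local twist is continued or reversed.  Its
shape is summarized by three internal coordinates:

* ``delta1`` — virtual dihedral over Cα1–Cα2–Cα3–Cα4 (degrees),
* ``delta2`` — virtual dihedral over Cα2–Cα3–Cα4–Cα5 (degrees),
* ``kappa``  — the Cα1–Cα5 distance (Å), a compactness descriptor.

Each descriptor is trichotomized into the states ``alpha`` / ``beta`` /
``other``, so the descriptor space is a 3×3×3 cube of 27 cells.  Every
cell is a folding shape and carries one symbol of the PFSC alphabet:
the 26 letters A–Z plus ``$``.  ``A`` is the typical α-helix shape
(all-``alpha`` cell) and ``B`` the typical β-strand shape (all-``beta``
cell); Y, P, D, H carry partial helix character, E, G, S, M partial
strand character, V and J mix helix and strand, and the remaining 15
symbols cover irregular tertiary shapes.  Any Cα trace therefore maps to
a gap-free shape string of length ``L - 4``.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
from typing import Iterable, NamedTuple

import numpy as np
from scipy.optimize import brentq

from .config import DEFAULT_CALIBRATION, Calibration

__all__ = [
    "ALPHABET",
    "CELL_TO_SYMBOL",
    "CATrace",
    "DegenerateGeometryError",
    "FragmentDescriptors",
    "PFSCCode",
    "UNRESOLVED",
    "classify_descriptors",
    "classify_fragment",
    "code_class",
    "cube_neighbors",
    "encode_structure",
    "dihedral",
    "place_next_ca",
    "representative_fragment",
    "virtual_descriptors",
]

#: Marker emitted for windows that cannot be classified (chain break, …).
UNRESOLVED = "?"

# Descriptor states, ordered so that ``other`` sits between ``alpha`` and
# ``beta`` on every axis: on the dihedral axes the ``other`` range
# geometrically separates the helix bin from the circular strand bin, and
# on the compactness axis intermediate distances separate compact from
# extended.  Cube adjacency (one step on one axis) relies on this order.
ALPHA, BETA, OTHER = "alpha", "beta", "other"
_STATE_ORDER = (ALPHA, OTHER, BETA)

HELIX = "helix"
PARTIAL_HELIX = "partial_helix"
STRAND = "strand"
PARTIAL_STRAND = "partial_strand"
MIXED = "mixed"
IRREGULAR = "irregular"


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined (collinear consecutive points)."""


class FragmentDescriptors(NamedTuple):
    """Internal coordinates of a 5-point Cα fragment."""

    delta1: float  # degrees, virtual dihedral Cα1..Cα4
    delta2: float  # degrees, virtual dihedral Cα2..Cα5
    kappa: float  # Å, Cα1–Cα5 distance


@dataclasses.dataclass(frozen=True)
class PFSCCode:
    """One symbol of the 27-letter folding-shape alphabet."""

    symbol: str
    ss_class: str
    cell: tuple[str, str, str]  # states of (delta1, delta2, kappa)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol


# ---------------------------------------------------------------------------
# The frozen cell → symbol table.
#
# Class membership follows the published letter lists; the letter-to-cell
# choice within each class is a frozen package convention (only class-level
# semantics are externally constrained).  States are (delta1, delta2, kappa).
_A, _B, _O = ALPHA, BETA, OTHER
CELL_TO_SYMBOL: dict[tuple[str, str, str], str] = {
    (_A, _A, _A): "A",  # typical alpha helix
    (_B, _B, _B): "B",  # typical beta strand
}
# Partial helix: both dihedrals helical but kappa off, or one helical
# dihedral with helical compactness.
for _cell, _sym in zip(
    [(_A, _A, _O), (_A, _A, _B), (_A, _O, _A), (_O, _A, _A)], "YPDH"
):
    CELL_TO_SYMBOL[_cell] = _sym
# Partial strand, mirrored.
for _cell, _sym in zip(
    [(_B, _B, _O), (_B, _B, _A), (_B, _O, _B), (_O, _B, _B)], "EGSM"
):
    CELL_TO_SYMBOL[_cell] = _sym
# Mixed helix/strand character.
CELL_TO_SYMBOL[(_A, _B, _O)] = "V"
CELL_TO_SYMBOL[(_B, _A, _O)] = "J"
# The remaining 15 cells are irregular; assign letters in lexicographic
# cell order using the published irregular-letter order.
_REMAINING = sorted(
    cell
    for cell in itertools.product((_A, _B, _O), repeat=3)
    if cell not in CELL_TO_SYMBOL
)
for _cell, _sym in zip(_REMAINING, "XURIFLOCZWTK$NQ"):
    CELL_TO_SYMBOL[_cell] = _sym

_CLASS_OF_SYMBOL = {
    "A": HELIX,
    "B": STRAND,
    **{s: PARTIAL_HELIX for s in "YPDH"},
    **{s: PARTIAL_STRAND for s in "EGSM"},
    **{s: MIXED for s in "VJ"},
}

#: symbol → :class:`PFSCCode` for the full 27-letter alphabet.
ALPHABET: dict[str, PFSCCode] = {
    sym: PFSCCode(sym, _CLASS_OF_SYMBOL.get(sym, IRREGULAR), cell)
    for cell, sym in CELL_TO_SYMBOL.items()
}
assert len(ALPHABET) == 27 and set(CELL_TO_SYMBOL) == set(
    itertools.product((_A, _B, _O), repeat=3)
)


# ---------------------------------------------------------------------------
# Cα traces


@dataclasses.dataclass
class CATrace:
    """An ordered Cα trace: one-letter residues plus coordinates in Å."""

    residues: str
    coords: np.ndarray  # shape (L, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (L, 3)")
        if len(self.residues) != len(self.coords):
            raise ValueError(
                f"{len(self.residues)} residues but {len(self.coords)} coordinates"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residues)

    def bond_lengths(self) -> np.ndarray:
        """Consecutive Cα–Cα distances (length ``L - 1``)."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def window(self, i: int) -> np.ndarray:
        """Coordinates of the 0-based window ``i`` (residues i..i+4)."""
        return self.coords[i : i + 5]


# ---------------------------------------------------------------------------
# Descriptors


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion of four ordered points, in degrees on (-180, 180].

    Raises :class:`DegenerateGeometryError` when three consecutive points
    are collinear, which leaves the torsion undefined.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0 or min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-9:
        raise DegenerateGeometryError("torsion undefined: collinear points")
    m1 = np.cross(n1, b2 / b2n)
    angle = float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))
    return 180.0 if angle == -180.0 else angle


def virtual_descriptors(frag: np.ndarray) -> FragmentDescriptors:
    """Compute (delta1, delta2, kappa) for a 5-point Cα fragment."""
    frag = np.asarray(frag, dtype=float)
    if frag.shape != (5, 3):
        raise ValueError("fragment must contain exactly 5 points")
    if not np.isfinite(frag).all():
        raise ValueError("fragment coordinates must be finite")
    if (np.linalg.norm(np.diff(frag, axis=0), axis=1) == 0.0).any():
        raise ValueError("consecutive points must not coincide")
    return FragmentDescriptors(
        delta1=dihedral(*frag[:4]),
        delta2=dihedral(*frag[1:5]),
        kappa=float(np.linalg.norm(frag[4] - frag[0])),
    )


def _dihedral_state(d: float, cal: Calibration) -> str:
    if cal.helix_dihedral_lo <= d < cal.helix_dihedral_hi:
        return ALPHA
    if d >= cal.strand_dihedral_min or d < -cal.strand_dihedral_min:
        return BETA  # circular bin across the ±180° branch cut
    return OTHER


def _kappa_state(k: float, cal: Calibration) -> str:
    if k < cal.kappa_compact_max:
        return ALPHA
    if k < cal.kappa_extended_min:
        return OTHER
    return BETA


def classify_descriptors(
    d: FragmentDescriptors, cal: Calibration = DEFAULT_CALIBRATION
) -> PFSCCode:
    """Bin the three descriptors and return the cell's unique symbol.

    The bins tile the full descriptor range with half-open intervals, so
    the map is total and boundary values are assigned deterministically.
    """
    if not all(np.isfinite(v) for v in d):
        raise ValueError("descriptors must be finite")
    cell = (
        _dihedral_state(d.delta1, cal),
        _dihedral_state(d.delta2, cal),
        _kappa_state(d.kappa, cal),
    )
    return ALPHABET[CELL_TO_SYMBOL[cell]]


def classify_fragment(
    frag: np.ndarray, cal: Calibration = DEFAULT_CALIBRATION
) -> PFSCCode:
    """Classify a 5-point Cα fragment into its folding-shape code."""
    return classify_descriptors(virtual_descriptors(frag), cal)


# ---------------------------------------------------------------------------
# Representative geometry


def place_next_ca(
    p_a: np.ndarray,
    p_b: np.ndarray,
    p_c: np.ndarray,
    angle: float,
    torsion_angle: float,
    bond: float,
) -> np.ndarray:
    """Append a point at a given bond length, bond angle and torsion.

    Standard internal-coordinate (NeRF-style) placement: the new point is
    bonded to ``p_c`` with the given virtual bond length, makes the given
    virtual bond angle at ``p_c`` and the given torsion about p_b–p_c
    relative to ``p_a``.
    """
    th, ph = np.radians(angle), np.radians(torsion_angle)
    bc = p_c - p_b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p_b - p_a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(th), bond * np.sin(th) * np.cos(ph), -bond * np.sin(th) * np.sin(ph)]
    )
    return p_c + d[0] * bc + d[1] * m + d[2] * n


def _fragment_from_internal(
    theta: float, d1: float, d2: float, bond: float
) -> np.ndarray:
    """5-point fragment with uniform bond angle ``theta`` and torsions d1, d2."""
    th = np.radians(theta)
    pts = [
        np.zeros(3),
        np.array([bond, 0.0, 0.0]),
        np.array([bond - bond * np.cos(th), bond * np.sin(th), 0.0]),
    ]
    pts.append(place_next_ca(pts[0], pts[1], pts[2], theta, d1, bond))
    pts.append(place_next_ca(pts[1], pts[2], pts[3], theta, d2, bond))
    return np.array(pts)


_DIH_CENTER_BY_STATE = {
    ALPHA: "helix_dihedral_center",
    BETA: "strand_dihedral_center",
    OTHER: "other_dihedral_center",
}
_KAPPA_CENTER_BY_STATE = {
    ALPHA: "kappa_compact_center",
    OTHER: "kappa_other_center",
    BETA: "kappa_extended_center",
}


def _representative_uncached(symbol: str, cal: Calibration) -> np.ndarray:
    code = ALPHABET[symbol]
    d1 = getattr(cal, _DIH_CENTER_BY_STATE[code.cell[0]])
    d2 = getattr(cal, _DIH_CENTER_BY_STATE[code.cell[1]])
    target = getattr(cal, _KAPPA_CENTER_BY_STATE[code.cell[2]])

    def gap(theta: float) -> float:
        frag = _fragment_from_internal(theta, d1, d2, cal.bond_length)
        return float(np.linalg.norm(frag[4] - frag[0])) - target

    # The Cα1–Cα5 distance is controlled through the (uniform) virtual bond
    # angle; scan for sign changes and refine the root nearest 110°, a
    # protein-like bond-angle regime.
    grid = np.linspace(45.0, 178.0, 220)
    vals = np.array([gap(t) for t in grid])
    best_theta = None
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0.0:
            theta = brentq(gap, grid[i], grid[i + 1], xtol=1e-10)
            if best_theta is None or abs(theta - 110.0) < abs(best_theta - 110.0):
                best_theta = theta
    if best_theta is None:  # pragma: no cover - defensive; all 27 resolve
        best_theta = float(grid[np.argmin(np.abs(vals))])
    frag = _fragment_from_internal(best_theta, d1, d2, cal.bond_length)
    frag.setflags(write=False)
    return frag


@functools.lru_cache(maxsize=64)
def _representative_cached(symbol: str, cal: Calibration) -> np.ndarray:
    return _representative_uncached(symbol, cal)


def representative_fragment(
    code: str | PFSCCode, cal: Calibration = DEFAULT_CALIBRATION
) -> np.ndarray:
    """Canonical 5-Cα geometry of a folding-shape code.

    Built from the code's cell-center descriptor values with 3.8 Å virtual
    bonds; re-classifying the result returns the same code.
    """
    symbol = code.symbol if isinstance(code, PFSCCode) else code
    if symbol not in ALPHABET:
        raise ValueError(f"unknown folding-shape code {symbol!r}")
    return _representative_cached(symbol, cal).copy()


# ---------------------------------------------------------------------------
# Whole-trace encoding


def encode_structure(
    trace: CATrace, cal: Calibration = DEFAULT_CALIBRATION
) -> str:
    """Encode a Cα trace as a folding-shape string of length ``L - 4``.

    The string describes the backbone without gaps: character ``i`` is the
    code of the window covering residues ``i..i+4`` (0-based).  Windows
    containing a chain break (a consecutive Cα–Cα distance outside the
    validity band) or a residue outside the 20-letter alphabet yield the
    unresolved marker ``?`` so that string positions stay aligned.
    """
    if len(trace) < 5:
        raise ValueError(f"trace has {len(trace)} residues; need at least 5")
    bonds = trace.bond_lengths()
    bond_ok = (bonds >= cal.bond_valid_lo) & (bonds <= cal.bond_valid_hi)
    from .library import CANONICAL_AA  # local import to avoid a cycle

    res_ok = np.array([r in CANONICAL_AA for r in trace.residues.upper()])
    out = []
    for i in range(len(trace) - 4):
        if bond_ok[i : i + 4].all() and res_ok[i : i + 5].all():
            out.append(classify_fragment(trace.window(i), cal).symbol)
        else:
            out.append(UNRESOLVED)
    return "".join(out)


# ---------------------------------------------------------------------------
# Alphabet topology


def code_class(code: str | PFSCCode) -> str:
    """The secondary-structure class of a code."""
    symbol = code.symbol if isinstance(code, PFSCCode) else code
    if symbol not in ALPHABET:
        raise ValueError(f"unknown folding-shape code {symbol!r}")
    return ALPHABET[symbol].ss_class


def cube_neighbors(code: str | PFSCCode) -> set[str]:
    """Codes whose cells are face-adjacent in the 3×3×3 descriptor cube.

    Two cells are adjacent when they differ on exactly one descriptor axis
    by one step of the state order ``alpha < other < beta``; adjacent codes
    share partial folding character.
    """
    symbol = code.symbol if isinstance(code, PFSCCode) else code
    if symbol not in ALPHABET:
        raise ValueError(f"unknown folding-shape code {symbol!r}")
    cell = ALPHABET[symbol].cell
    idx = tuple(_STATE_ORDER.index(s) for s in cell)
    out: set[str] = set()
    for axis in range(3):
        for step in (-1, 1):
            j = idx[axis] + step
            if 0 <= j < 3:
                nb = list(cell)
                nb[axis] = _STATE_ORDER[j]
                out.add(CELL_TO_SYMBOL[tuple(nb)])
    return out


def iter_alphabet() -> Iterable[PFSCCode]:
    """All 27 codes, alphabetically with ``$`` last."""
    return [ALPHABET[s] for s in sorted(ALPHABET, key=lambda s: (s == "$", s))]
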