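"""Build 3D Cα traces from folding-shape strings and sample ensembles.

A shape string fixes, window by window, the descriptor cell that every
five consecutive Cα atoms must occupy.  The builder realizes such a
string greedily: the first window is laid down as the first code's
representative fragment, and each further residue is appended by an
internal-coordinate placement chosen so that the newly completed window
lands inside its code's descriptor cell — the new virtual torsion is
searched within the code's dihedral bin, the free virtual bond angle is
searched over the protein-like range, and the candidate closest to the
cell-center compactness is kept.  Because the shared four atoms of
consecutive windows pin the first torsion of each new window, encoded
strings are self-consistent in that coordinate by construction; only
the compactness descriptor can be geometrically over-constrained, so a
one-step lookahead prefers candidates that keep the next window's
compactness bin reachable.  Earlier geometry is never revised.

Ensembles come from the variation matrix: every column offers
alternative codes, and strings are enumerated (top row, single
substitutions) or sampled column-independently with probability
proportional to the recorded counts.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy.spatial.transform import Rotation

from .config import DEFAULT_CALIBRATION, Calibration
from .geometry import (
    ALPHA,
    ALPHABET,
    BETA,
    CATrace,
    OTHER,
    UNRESOLVED,
    place_next_ca,
    representative_fragment,
)
from .matrix import PFVM, FoldColumn

__all__ = [
    "build_ca_trace",
    "enumerate_strings",
    "ensemble_spread",
    "superpose_rmsd",
]

logger = logging.getLogger(__name__)

#: Hard cap on enumerated/sampled strings (the full column product is
#: astronomically large for real sequences).
DEFAULT_STRING_CAP = 10_000


# ---------------------------------------------------------------------------
# Candidate grids for the greedy placement


def _dihedral_candidates(state: str, cal: Calibration) -> np.ndarray:
    margin = 2.0
    if state == ALPHA:
        return np.linspace(
            cal.helix_dihedral_lo + margin, cal.helix_dihedral_hi - margin, 11
        )
    if state == BETA:
        m = cal.strand_dihedral_min
        return np.concatenate(
            [np.linspace(m + margin, 178.0, 8), np.linspace(-178.0, -m - margin, 7)]
        )
    # 'other' covers two disjoint arcs between the helix and strand bins.
    lo_arc = np.linspace(-cal.strand_dihedral_min + margin, cal.helix_dihedral_lo - margin, 17)
    hi_arc = np.linspace(cal.helix_dihedral_hi + margin, cal.strand_dihedral_min - margin, 8)
    return np.concatenate([lo_arc, hi_arc])


_THETA_GRID = np.linspace(45.0, 178.0, 68)


def _kappa_bin(state: str, cal: Calibration) -> tuple[float, float, float]:
    """(low, high, center) of a compactness state."""
    if state == ALPHA:
        return 0.0, cal.kappa_compact_max, cal.kappa_compact_center
    if state == OTHER:
        return cal.kappa_compact_max, cal.kappa_extended_min, cal.kappa_other_center
    return cal.kappa_extended_min, 4.0 * cal.bond_length + 0.1, cal.kappa_extended_center


def _candidate_points(
    chain_tail: np.ndarray, d2_state: str, cal: Calibration
) -> tuple[np.ndarray, np.ndarray]:
    """All grid placements of the next Cα and their torsion values.

    Vectorized internal-coordinate placement over the (torsion, bond
    angle) candidate grid; equivalent to calling
    :func:`~pfvmkit.geometry.place_next_ca` per pair.
    """
    p_a, p_b, p_c = chain_tail[-3], chain_tail[-2], chain_tail[-1]
    torsions = _dihedral_candidates(d2_state, cal)
    bond = cal.bond_length
    bc = p_c - p_b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p_b - p_a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    th = np.radians(_THETA_GRID)[None, :]  # (1, T)
    ph = np.radians(torsions)[:, None]  # (P, 1)
    d0 = -bond * np.cos(th) + 0.0 * ph
    d1 = bond * np.sin(th) * np.cos(ph)
    d2 = -bond * np.sin(th) * np.sin(ph)
    pts = (
        p_c
        + d0[..., None] * bc
        + d1[..., None] * m
        + d2[..., None] * n
    ).reshape(-1, 3)
    return pts, np.repeat(torsions, len(_THETA_GRID))


def build_ca_trace(
    pfsc_string: str,
    sequence: str,
    cal: Calibration = DEFAULT_CALIBRATION,
) -> CATrace:
    """Construct a Cα trace realizing a folding-shape string.

    ``len(pfsc_string)`` must equal ``len(sequence) - 4`` and the string
    must be fully resolved (no ``?``).  A single-code string returns
    exactly the code's representative fragment; uniform strings of
    self-consistent codes (equal dihedral states, e.g. all-A or all-B)
    re-encode to themselves exactly.  All virtual bonds have the
    calibrated 3.8 Å length.
    """
    seq = sequence.strip().upper()
    if len(pfsc_string) != len(seq) - 4:
        raise ValueError(
            f"shape string of length {len(pfsc_string)} does not match "
            f"sequence of length {len(seq)} (need L - 4)"
        )
    bad = set(pfsc_string) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid folding-shape symbols {sorted(bad)!r}")

    chain = list(representative_fragment(pfsc_string[0], cal))
    for pos, symbol in enumerate(pfsc_string[1:], start=1):
        cell = ALPHABET[symbol].cell
        lo, hi, center = _kappa_bin(cell[2], cal)
        tail = np.array(chain[-4:])
        pts, torsions = _candidate_points(tail, cell[1], cal)
        kappas = np.linalg.norm(pts - tail[0], axis=1)
        in_bin = (kappas >= lo) & (kappas < hi)
        if in_bin.any():
            idx = np.flatnonzero(in_bin)
            # One-step lookahead: keep the next window's compactness bin
            # reachable (the new point becomes Cα2 of the next window, so
            # its distance to the current Cα3 bounds the achievable span).
            nxt = pfsc_string[pos + 1] if pos + 1 < len(pfsc_string) else None
            if nxt is not None:
                n_lo, n_hi, _ = _kappa_bin(ALPHABET[nxt].cell[2], cal)
                d_next = np.linalg.norm(pts[idx] - tail[1], axis=1)
                reachable = (np.abs(d_next - cal.bond_length) < n_hi) & (
                    d_next + cal.bond_length >= n_lo
                )
                if reachable.any():
                    idx = idx[reachable]
            pick = idx[np.argmin(np.abs(kappas[idx] - center))]
        else:
            # The target compactness bin is unreachable from the frozen
            # prefix; take the nearest-miss placement.
            pick = int(
                np.argmin(np.minimum(np.abs(kappas - lo), np.abs(kappas - hi)))
            )
        chain.append(pts[pick])
    return CATrace(seq, np.array(chain))


# ---------------------------------------------------------------------------
# String enumeration from a PFVM


def _covered_span(columns: list[FoldColumn]) -> tuple[int, int]:
    """Longest contiguous run of non-empty columns (0-based, half-open)."""
    best = (0, 0)
    start = None
    for i, col in enumerate(columns):
        if col.codes:
            if start is None:
                start = i
            if i + 1 - start > best[1] - best[0]:
                best = (start, i + 1)
        else:
            start = None
    return best


def enumerate_strings(
    pfvm: PFVM,
    mode: str = "top",
    k: int = DEFAULT_STRING_CAP,
    seed: int | None = None,
) -> list[str]:
    """Folding-shape strings drawn from a variation matrix.

    Modes: ``top`` — the single first-ranked string; ``substitute_one`` —
    the top string plus every single-column replacement (capped at ``k``);
    ``sample`` — ``k`` strings drawn column-independently with
    probability proportional to the recorded counts, reproducible under
    ``seed``.  When the matrix has empty columns, strings cover the
    longest contiguous non-empty span only.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("top", "substitute_one", "sample"):
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = _covered_span(pfvm.columns)
    if hi == lo:
        raise ValueError("matrix has no non-empty column")
    if (lo, hi) != (0, len(pfvm.columns)):
        logger.info(
            "restricting to covered windows %d..%d of %d", lo + 1, hi, len(pfvm.columns)
        )
    columns = pfvm.columns[lo:hi]
    top = "".join(c.codes[0][0] for c in columns)
    if mode == "top":
        return [top]
    if mode == "substitute_one":
        out = [top]
        for i, col in enumerate(columns):
            for symbol, _ in col.codes[1:]:
                if len(out) == k:
                    logger.warning("substitution enumeration capped at %d", k)
                    return out
                out.append(top[:i] + symbol + top[i + 1 :])
        return out
    rng = np.random.default_rng(seed)
    picks = []
    for col in columns:
        symbols = [s for s, _ in col.codes]
        counts = np.array([c for _, c in col.codes], dtype=float)
        total = counts.sum()
        probs = counts / total if total > 0 else np.full(len(symbols), 1 / len(symbols))
        picks.append(rng.choice(symbols, size=k, p=probs))
    return ["".join(row) for row in np.array(picks).T]


def string_span_sequence(pfvm: PFVM) -> str:
    """Sub-sequence spanned by the strings of :func:`enumerate_strings`."""
    lo, hi = _covered_span(pfvm.columns)
    if hi == lo:
        raise ValueError("matrix has no non-empty column")
    return pfvm.sequence[lo : hi + 4]


# ---------------------------------------------------------------------------
# Ensemble geometry


def superpose_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD of two equal-length point sets after least-squares rigid fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("point sets must have equal shape")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, _ = Rotation.align_vectors(xc, yc)
    return float(np.sqrt(np.mean(np.sum((xc - rot.apply(yc)) ** 2, axis=1))))


def ensemble_spread(traces: list[CATrace]) -> np.ndarray:
    """Pairwise superposed-RMSD matrix of an ensemble (Å)."""
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError("traces must have equal length")
    n = len(traces)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = superpose_rmsd(traces[i].coords, traces[j].coords)
    return out
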