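"""Synthetic inputs: ideal traces, random coils and seed libraries.

Everything the package needs for calibration, testing and demonstration
is generated here programmatically — no structure downloads.  The ideal
helix and strand are the calibration standards of the alphabet (they
encode to uniform 'A' and 'B' strings); random coils probe the irregular
sector; and :func:`worked_example_table` carries a small curated set of
5-mer → shape mappings used as the package's worked example.
"""

from __future__ import annotations

import logging

import numpy as np

from .geometry import CATrace, place_next_ca
from .library import CANONICAL_AA, KEY_SPACE, FoldLookupTable

__all__ = [
    "make_ideal_helix",
    "make_ideal_strand",
    "make_random_coil",
    "random_library",
    "random_sequence",
    "worked_example_table",
]

logger = logging.getLogger(__name__)

#: Ideal α-helix Cα geometry: rise per residue (Å), helix radius (Å) and
#: rotation per residue (degrees).  Right-handed, giving the +50° virtual
#: torsion characteristic of real α-helices.
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST = 100.0

#: Ideal extended strand: planar zigzag with 3.8 Å virtual bonds and this
#: virtual bond angle (degrees); the virtual torsion is exactly 180°.
STRAND_ANGLE = 120.0
BOND = 3.8


def _default_sequence(n: int, sequence: str | None, seed: int | None) -> str:
    if sequence is not None:
        if len(sequence) != n:
            raise ValueError("sequence length must equal n")
        return sequence.upper()
    if seed is not None:
        return random_sequence(n, seed)
    return "A" * n


def random_sequence(n: int, seed: int | None = None) -> str:
    """Uniform random sequence over the 20 canonical amino acids."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(CANONICAL_AA), size=n))


def make_ideal_helix(
    n: int, sequence: str | None = None, seed: int | None = None
) -> CATrace:
    """Cα trace of an ideal right-handed α-helix (n ≥ 5).

    Points lie on a circular helix with 1.5 Å rise, 2.3 Å radius and
    100°/residue twist; consecutive Cα distances are ≈ 3.83 Å and the
    whole trace encodes to an all-'A' shape string.
    """
    if n < 5:
        raise ValueError("need at least 5 residues")
    omega = np.radians(HELIX_TWIST)
    i = np.arange(n)
    coords = np.column_stack(
        [
            HELIX_RADIUS * np.cos(-omega * i),
            HELIX_RADIUS * np.sin(-omega * i),
            HELIX_RISE * i,
        ]
    )
    return CATrace(_default_sequence(n, sequence, seed), coords)


def make_ideal_strand(
    n: int, sequence: str | None = None, seed: int | None = None
) -> CATrace:
    """Cα trace of an ideal extended strand (planar zigzag, n ≥ 5).

    3.8 Å virtual bonds with a 120° virtual bond angle; encodes to an
    all-'B' shape string.
    """
    if n < 5:
        raise ValueError("need at least 5 residues")
    half = np.radians(STRAND_ANGLE / 2.0)
    i = np.arange(n)
    coords = np.column_stack(
        [
            BOND * np.sin(half) * i,
            (BOND * np.cos(half) / 2.0) * (-1.0) ** i,
            np.zeros(n),
        ]
    )
    return CATrace(_default_sequence(n, sequence, seed), coords)


def make_random_coil(n: int, seed: int | None = None) -> CATrace:
    """Self-avoiding-ish random Cα chain with 3.8 Å virtual bonds.

    Virtual torsions are drawn uniformly on (-180, 180] and virtual bond
    angles uniformly on [80°, 140°]; reproducible under ``seed``.  The
    encoded string mixes helix-, strand- and irregular-class codes.
    """
    if n < 5:
        raise ValueError("need at least 5 residues")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(80.0, 140.0)
    pts = [
        np.zeros(3),
        np.array([BOND, 0.0, 0.0]),
        np.array(
            [
                BOND - BOND * np.cos(np.radians(theta0)),
                BOND * np.sin(np.radians(theta0)),
                0.0,
            ]
        ),
    ]
    for _ in range(n - 3):
        pts.append(
            place_next_ca(
                pts[-3],
                pts[-2],
                pts[-1],
                rng.uniform(80.0, 140.0),
                rng.uniform(-180.0, 180.0),
                BOND,
            )
        )
    return CATrace(random_sequence(n, seed), np.array(pts))


# Curated 5-mer → ranked-code mappings used as the worked example.  The
# printed source list for GEGNG contains the letter 'S' twice; the
# duplicate is collapsed here (11 distinct codes) and noted when built.
_WORKED_EXAMPLE = {
    "MEDSQ": "AD",
    "EDSQS": "PADV",
    "DSQSD": "AEV",
    "SQSDM": "AERVBSWY",
    "DWLGE": "DA",
    "EQLLE": "ADYP",
    "EKKKG": "JCEVSABWQLPDYZ",
    "GEGNG": "WBZCESLPVARS",
}


def worked_example_table() -> FoldLookupTable:
    """Small curated lookup table for the worked example.

    Ranks follow the curated order, encoded as strictly decreasing
    synthetic counts (the source gives order, not frequencies).
    """
    table = FoldLookupTable(provenance="curated worked example")
    for fivemer, codes in _WORKED_EXAMPLE.items():
        unique = list(dict.fromkeys(codes))
        if len(unique) != len(codes):
            logger.debug(
                "%s: %d duplicate code(s) collapsed from curated list",
                fivemer,
                len(codes) - len(unique),
            )
        for rank, symbol in enumerate(unique):
            table.add_observation(fivemer, symbol, count=len(unique) - rank)
    return table


def random_library(
    seed: int | None, n_keys: int, max_codes: int = 27
) -> FoldLookupTable:
    """Random lookup table: ``n_keys`` distinct 5-mers, 1..max_codes codes each.

    Counts are uniform on 1..100; deterministic under ``seed``.
    """
    if not 1 <= max_codes <= 27:
        raise ValueError("max_codes must be in 1..27")
    if not 1 <= n_keys <= KEY_SPACE:
        raise ValueError(f"n_keys must be in 1..{KEY_SPACE}")
    rng = np.random.default_rng(seed)
    from .geometry import ALPHABET

    symbols = sorted(ALPHABET)
    table = FoldLookupTable(provenance=f"random library (seed={seed})")
    keys: set[str] = set()
    alphabet = list(CANONICAL_AA)
    while len(keys) < n_keys:
        keys.add("".join(rng.choice(alphabet, size=5)))
    for key in sorted(keys):
        n_codes = int(rng.integers(1, max_codes + 1))
        for symbol in rng.choice(symbols, size=n_codes, replace=False):
            table.add_observation(key, symbol, int(rng.integers(1, 101)))
    return table
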