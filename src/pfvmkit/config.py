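"""Calibration constants for the folding-shape alphabet.

All geometric bin boundaries used to discretize a 5-residue Cα fragment
into one of the 27 folding-shape cells live here, together with the
virtual-bond parameters shared by the encoder, the fragment library and
the conformer builder.  The constants can be overridden from a simple
``key = value`` text file so that alternative calibrations are possible
without touching code; the shipped defaults are anchored on ideal
secondary-structure geometry (see ``docs/methods.md``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

#: Version tag of the frozen cell→symbol table shipped with this package.
TABLE_VERSION = "pfsc27-v1"


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Bin boundaries and virtual-bond parameters.

    Dihedral angles are in degrees on (-180, 180]; distances in Å.

    * A virtual dihedral is *helix-like* (state ``alpha``) when it lies in
      ``[helix_dihedral_lo, helix_dihedral_hi)``.
    * It is *strand-like* (state ``beta``) when ``|d| >= strand_dihedral_min``;
      this bin is circular, wrapping across the ±180° branch cut.
    * The compactness descriptor (Cα1–Cα5 distance) is ``alpha`` below
      ``kappa_compact_max``, ``beta`` at or above ``kappa_extended_min``,
      ``other`` in between.
    """

    helix_dihedral_lo: float = 20.0
    helix_dihedral_hi: float = 80.0
    strand_dihedral_min: float = 150.0

    kappa_compact_max: float = 8.0
    kappa_extended_min: float = 11.0

    # Bin-center values used when constructing representative geometry.
    helix_dihedral_center: float = 50.0
    strand_dihedral_center: float = 180.0
    other_dihedral_center: float = -60.0
    kappa_compact_center: float = 6.2
    kappa_other_center: float = 9.5
    kappa_extended_center: float = 13.0

    # Virtual Cα–Cα bond.
    bond_length: float = 3.8
    bond_valid_lo: float = 2.8
    bond_valid_hi: float = 4.3

    table_version: str = TABLE_VERSION

    # Numeric tolerance for geometric comparisons (degrees / Å).
    tol: float = 1e-6

    def to_file(self, path: str | Path) -> None:
        """Write the calibration as ``key = value`` lines."""
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Calibration":
        """Load a calibration, falling back to defaults for absent keys."""
        overrides: dict[str, object] = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in field_types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            overrides[key] = value if key == "table_version" else float(value)
        return cls(**overrides)  # type: ignore[arg-type]


#: Default calibration used throughout the package.
DEFAULT_CALIBRATION = Calibration()
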