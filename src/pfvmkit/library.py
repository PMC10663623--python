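"""The 5-mer → folding-shape lookup library.

Maps every sequence 5-mer over the 20 canonical amino acids to the ranked
set of folding-shape codes observed for it in a structure collection,
with observation counts.  The key space is bounded by 20^5 = 3,200,000
possible 5-mers and each entry holds at most the 27 codes of the
alphabet.  Ranking is by descending count with lexicographic tie-break
('$' sorts last), so the first-ranked code of an entry is the most
frequently observed shape for that 5-mer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

from .config import TABLE_VERSION, Calibration, DEFAULT_CALIBRATION
from .geometry import ALPHABET, UNRESOLVED, CATrace, encode_structure

__all__ = [
    "CANONICAL_AA",
    "KEY_SPACE",
    "FoldLookupTable",
    "TableParseError",
    "build_from_structures",
]

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids (one-letter, alphabetical).
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Number of possible 5-mers over the canonical alphabet.
KEY_SPACE = len(CANONICAL_AA) ** 5  # == 3,200,000


class TableParseError(ValueError):
    """Malformed lookup-table file."""


def _rank_key(item: tuple[str, int]) -> tuple[int, bool, str]:
    symbol, count = item
    return (-count, symbol == "$", symbol)


def _validate_fivemer(fivemer: str) -> str:
    if len(fivemer) != 5:
        raise ValueError(f"5-mer key must have length 5, got {fivemer!r}")
    key = fivemer.upper()
    if any(aa not in CANONICAL_AA for aa in key):
        raise ValueError(f"5-mer {fivemer!r} outside the 20-letter alphabet")
    return key


@dataclasses.dataclass
class FoldLookupTable:
    """Ranked 5-mer → [(code, count), …] lookup table."""

    entries: dict[str, list[tuple[str, int]]] = dataclasses.field(
        default_factory=dict
    )
    provenance: str = ""
    version: str = TABLE_VERSION

    # -- construction -------------------------------------------------------

    def add_observation(self, fivemer: str, symbol: str, count: int = 1) -> None:
        """Add ``count`` observations of ``symbol`` under ``fivemer``."""
        key = _validate_fivemer(fivemer)
        if symbol not in ALPHABET:
            raise ValueError(f"unknown folding-shape code {symbol!r}")
        if count < 0:
            raise ValueError("count must be nonnegative")
        entry = dict(self.entries.get(key, []))
        entry[symbol] = entry.get(symbol, 0) + count
        self.entries[key] = sorted(entry.items(), key=_rank_key)

    # -- queries -------------------------------------------------------------

    def query(self, fivemer: str, fallback: bool = False) -> list[tuple[str, int]]:
        """Ranked codes observed for a 5-mer; empty when unrecorded.

        With ``fallback=True`` an unrecorded 5-mer is answered by pooling
        the codes of all stored keys sharing a 4-mer overlap with it (a
        documented extension, off by default; counts are summed over the
        overlapping keys and re-ranked).
        """
        key = _validate_fivemer(fivemer)
        hit = self.entries.get(key, [])
        if hit or not fallback:
            return list(hit)
        pooled: dict[str, int] = {}
        fourmers = {key[:4], key[1:]}
        for other, codes in self.entries.items():
            if other != key and ({other[:4], other[1:]} & fourmers):
                for symbol, count in codes:
                    pooled[symbol] = pooled.get(symbol, 0) + count
        return sorted(pooled.items(), key=_rank_key)

    def __contains__(self, fivemer: str) -> bool:
        return _validate_fivemer(fivemer) in self.entries

    def total_count(self) -> int:
        return sum(c for codes in self.entries.values() for _, c in codes)

    def coverage_stats(self) -> tuple[int, float]:
        """(number of keys, fraction of the 3,200,000-key space)."""
        n = len(self.entries)
        return n, n / KEY_SPACE

    # -- combination ---------------------------------------------------------

    def merge(self, other: "FoldLookupTable") -> "FoldLookupTable":
        """Key-wise count addition; requires matching versions."""
        if self.version != other.version:
            raise ValueError(
                f"version mismatch: {self.version!r} vs {other.version!r}"
            )
        merged = FoldLookupTable(
            provenance="+".join(p for p in (self.provenance, other.provenance) if p)
            or self.provenance,
            version=self.version,
        )
        for table in (self, other):
            for key, codes in table.entries.items():
                for symbol, count in codes:
                    merged.add_observation(key, symbol, count)
        return merged

    # -- persistence ---------------------------------------------------------

    def write(self, path: str | Path, fmt: str | None = None) -> None:
        """Write as TSV (`FIVEMER<TAB>code:count,…`) or JSON."""
        path = Path(path)
        fmt = fmt or ("json" if path.suffix == ".json" else "tsv")
        if fmt == "tsv":
            lines = [
                f"# pfvmkit fold lookup table",
                f"# version={self.version}",
                f"# provenance={self.provenance}",
            ]
            for key in sorted(self.entries):
                codes = ",".join(f"{s}:{c}" for s, c in self.entries[key])
                lines.append(f"{key}\t{codes}")
            path.write_text("\n".join(lines) + "\n")
        elif fmt == "json":
            payload = {
                "version": self.version,
                "provenance": self.provenance,
                "entries": {
                    key: [[s, c] for s, c in codes]
                    for key, codes in sorted(self.entries.items())
                },
            }
            path.write_text(json.dumps(payload, indent=1) + "\n")
        else:
            raise ValueError(f"unknown table format {fmt!r}")

    @classmethod
    def read(cls, path: str | Path) -> "FoldLookupTable":
        """Read a table written by :meth:`write` (format auto-detected)."""
        path = Path(path)
        text = path.read_text()
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
            table = cls(
                provenance=payload.get("provenance", ""),
                version=payload.get("version", TABLE_VERSION),
            )
            for key, codes in payload["entries"].items():
                if key in table.entries:
                    raise TableParseError(f"duplicate key {key!r} in {path}")
                for symbol, count in codes:
                    table.add_observation(key, symbol, int(count))
            return table
        table = cls()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# version="):
                    table.version = line.split("=", 1)[1]
                elif line.startswith("# provenance="):
                    table.provenance = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableParseError(f"{path}:{lineno}: expected 2 columns")
            key, codes_field = parts
            try:
                key = _validate_fivemer(key)
            except ValueError as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from exc
            if key in table.entries:
                raise TableParseError(f"{path}:{lineno}: duplicate key {key!r}")
            for item in codes_field.split(","):
                try:
                    symbol, count = item.split(":")
                    table.add_observation(key, symbol, int(count))
                except (ValueError, KeyError) as exc:
                    raise TableParseError(
                        f"{path}:{lineno}: bad code entry {item!r}"
                    ) from exc
        return table


def build_from_structures(
    records: Iterable[CATrace],
    cal: Calibration = DEFAULT_CALIBRATION,
    provenance: str = "",
) -> FoldLookupTable:
    """Tally folding-shape codes per 5-mer over a structure collection.

    Every valid 5-residue window of every trace contributes one
    observation of its classified code under its sequence 5-mer.
    Unresolved windows (chain breaks, non-canonical residues) are skipped
    with a logged warning; traces shorter than 5 residues raise.
    """
    table = FoldLookupTable(provenance=provenance)
    n_skipped = 0
    for trace in records:
        shape_string = encode_structure(trace, cal)
        seq = trace.residues.upper()
        for i, symbol in enumerate(shape_string):
            if symbol == UNRESOLVED:
                n_skipped += 1
                continue
            table.add_observation(seq[i : i + 5], symbol)
    if n_skipped:
        logger.warning("skipped %d unresolved windows while building", n_skipped)
    return table
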