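"""The protein folding variation matrix (PFVM).

For a sequence of length ``L`` the matrix has one column per 5-residue
window — ``L - 4`` columns, each aligned to the window's center residue
(position ``window + 2`` in 1-based numbering).  A column lists every
folding-shape code recorded for the window's 5-mer in a lookup library,
ranked most-probable first.  The per-column code count is the local
*disorder degree*: a 5-mer with one recorded shape is conformationally
rigid, one with many shapes is flexible, and the moving average of the
counts along the sequence traces the disorder profile of the protein.
The first-ranked code of every column concatenates to the "top string",
the single most probable folding conformation.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import click
import numpy as np

from .geometry import (
    ALPHABET,
    HELIX,
    IRREGULAR,
    MIXED,
    PARTIAL_HELIX,
    PARTIAL_STRAND,
    STRAND,
    UNRESOLVED,
)
from .library import CANONICAL_AA, FoldLookupTable

__all__ = [
    "DisorderProfile",
    "FoldColumn",
    "PFVM",
    "assemble_pfvm",
    "column_counts",
    "diff_pfvm",
    "disorder_profile",
    "interval_length",
    "render_text",
    "ss_tendency",
    "top_string",
]


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive residue interval [start, end]."""
    if end < start:
        raise ValueError(f"empty interval [{start}, {end}]")
    return end - start + 1


@dataclasses.dataclass
class FoldColumn:
    """One PFVM column: the ranked codes of a 5-residue window."""

    window_index: int  # 1-based window ordinal
    fivemer: str
    codes: list[tuple[str, int]]  # ranked (symbol, count); may be empty

    @property
    def center_residue(self) -> int:
        """1-based sequence position of the window's middle residue."""
        return self.window_index + 2

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.codes]


@dataclasses.dataclass
class PFVM:
    """Per-sequence folding variation matrix (one column per window)."""

    sequence: str
    columns: list[FoldColumn]

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def depth(self) -> int:
        """Largest column size (0 for an all-empty matrix)."""
        return max((len(c.codes) for c in self.columns), default=0)

    def to_json(self) -> str:
        payload = {
            "sequence": self.sequence,
            "columns": [
                {
                    "window": c.window_index,
                    "center_residue": c.center_residue,
                    "fivemer": c.fivemer,
                    "codes": [[s, n] for s, n in c.codes],
                }
                for c in self.columns
            ],
        }
        return json.dumps(payload, indent=1)


def assemble_pfvm(sequence: str, table: FoldLookupTable) -> PFVM:
    """Assemble the PFVM of a sequence from a lookup table.

    Each window advances by one residue, sharing four residues with its
    predecessor; column contents are the table's ranked answer for the
    window's 5-mer, verbatim.  Windows containing residues outside the
    canonical alphabet (or 5-mers absent from the table) give empty
    columns rather than errors.
    """
    seq = sequence.strip().upper()
    if len(seq) < 5:
        raise ValueError(f"sequence of length {len(seq)}; need at least 5")
    columns = []
    for i in range(len(seq) - 4):
        fivemer = seq[i : i + 5]
        if all(aa in CANONICAL_AA for aa in fivemer):
            codes = table.query(fivemer)
        else:
            codes = []
        columns.append(FoldColumn(window_index=i + 1, fivemer=fivemer, codes=codes))
    return PFVM(sequence=seq, columns=columns)


def top_string(pfvm: PFVM, row: int = 1) -> str:
    """The folding-shape string formed by the row-th code of each column.

    ``row=1`` is the most probable conformation.  Columns with fewer than
    ``row`` codes yield the unresolved marker ``?``.
    """
    if row < 1:
        raise ValueError("row must be >= 1")
    return "".join(
        c.codes[row - 1][0] if len(c.codes) >= row else UNRESOLVED
        for c in pfvm.columns
    )


def column_counts(pfvm: PFVM) -> np.ndarray:
    """Disorder degree D(i): number of codes in each column."""
    return np.array([len(c.codes) for c in pfvm.columns], dtype=int)


@dataclasses.dataclass
class DisorderProfile:
    """Per-column disorder degrees with their moving average and regions."""

    counts: np.ndarray  # D(i), one per column
    smoothed: np.ndarray  # S(i), centered moving average of D
    window: int
    regions: list[tuple[int, int, str]]  # 1-based inclusive residue spans

    def to_tsv(self) -> str:
        lines = ["center_residue\tD\tS"]
        for i, (d, s) in enumerate(zip(self.counts, self.smoothed)):
            lines.append(f"{i + 3}\t{d}\t{s:.4f}")
        return "\n".join(lines) + "\n"


def disorder_profile(pfvm: PFVM, window: int = 5) -> DisorderProfile:
    """Disorder degrees, their moving average and a region segmentation.

    ``S(i)`` is the arithmetic mean of ``D`` over the ``window`` columns
    centered at ``i``, truncated (not padded) at the matrix edges.
    Regions label contiguous runs of high / medium / low disorder by
    tertiles of ``S`` — a reporting convention, extended to the terminal
    residues that have no centered window of their own.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd positive integer")
    counts = column_counts(pfvm)
    half = window // 2
    n = len(counts)
    smoothed = np.array(
        [counts[max(0, i - half) : min(n, i + half + 1)].mean() for i in range(n)]
    )
    # Tertile segmentation of the smoothed curve.
    lo_cut, hi_cut = np.quantile(smoothed, [1 / 3, 2 / 3])
    labels = np.where(
        smoothed <= lo_cut, "low", np.where(smoothed <= hi_cut, "medium", "high")
    )
    regions: list[tuple[int, int, str]] = []
    seq_len = len(pfvm.sequence)
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            first = 1 if start == 0 else start + 3  # extend first region to N-term
            last = seq_len if i == n else i + 2  # and last region to C-term
            regions.append((first, last, str(labels[start])))
            start = i
    return DisorderProfile(
        counts=counts, smoothed=smoothed, window=window, regions=regions
    )


_HELIX_POOL = {HELIX, PARTIAL_HELIX}
_STRAND_POOL = {STRAND, PARTIAL_STRAND}


def ss_tendency(pfvm: PFVM, top_rows: int = 2) -> list[str]:
    """Per-column secondary-structure tendency from the top-ranked codes.

    The classes of the first ``top_rows`` codes are pooled into helix
    (helix + partial helix), strand (strand + partial strand) and
    irregular votes; mixed-class codes contribute half a vote to both the
    helix and strand pools.  The majority pool labels the column; exact
    ties give ``'ambiguous'`` and empty columns ``'unknown'``.
    """
    if top_rows < 1:
        raise ValueError("top_rows must be >= 1")
    out = []
    for col in pfvm.columns:
        if not col.codes:
            out.append("unknown")
            continue
        votes = {"helix": 0.0, "strand": 0.0, "irregular": 0.0}
        for symbol, _ in col.codes[:top_rows]:
            cls = ALPHABET[symbol].ss_class
            if cls in _HELIX_POOL:
                votes["helix"] += 1.0
            elif cls in _STRAND_POOL:
                votes["strand"] += 1.0
            elif cls == MIXED:
                votes["helix"] += 0.5
                votes["strand"] += 0.5
            else:
                votes["irregular"] += 1.0
        best = max(votes.values())
        winners = [k for k, v in votes.items() if v == best]
        out.append(winners[0] if len(winners) == 1 else "ambiguous")
    return out


def diff_pfvm(
    pfvm_ref: PFVM, pfvm_alt: PFVM
) -> list[tuple[int, set[str], set[str]]]:
    """Columns whose code sets differ between two equal-length matrices.

    Returns ``(center_residue, codes_removed, codes_added)`` triples;
    a single residue substitution can touch at most the five windows
    covering it.
    """
    if len(pfvm_ref.sequence) != len(pfvm_alt.sequence):
        raise ValueError("sequences must have equal length")
    out = []
    for ref_col, alt_col in zip(pfvm_ref.columns, pfvm_alt.columns):
        ref_set, alt_set = set(ref_col.symbols), set(alt_col.symbols)
        if ref_set != alt_set:
            out.append((ref_col.center_residue, ref_set - alt_set, alt_set - ref_set))
    return out


_CLASS_STYLE = {
    HELIX: {"fg": "red"},
    PARTIAL_HELIX: {"fg": "bright_magenta"},
    STRAND: {"fg": "blue"},
    PARTIAL_STRAND: {"fg": "bright_cyan"},
    # Mixed codes carry both partial-helix and partial-strand character;
    # rendered with the dual pink-on-blue tag.
    MIXED: {"fg": "bright_magenta", "underline": True},
    IRREGULAR: {},
}


def _styled(symbol: str, color: bool) -> str:
    if not color or symbol in (UNRESOLVED, "·", " "):
        return symbol
    style = _CLASS_STYLE[ALPHABET[symbol].ss_class]
    return click.style(symbol, **style) if style else symbol


def render_text(
    pfvm: PFVM,
    profile: DisorderProfile | None = None,
    color: bool = False,
    block_width: int = 60,
) -> str:
    """Plain-text (optionally ANSI-colored) rendering of a PFVM.

    Layout per block: a position ruler, the sequence row, then one row
    per rank with the rank-r code of every column under the column's
    center residue.  Empty columns show ``·`` in the first rank row;
    positions without a centered column (the two residues at each
    terminus) are blank.  With ``profile`` given, the rounded disorder
    curve is appended.  The symbols are identical with and without color.
    """
    seq = pfvm.sequence
    L = len(seq)
    depth = max(pfvm.depth, 1)
    by_center = {c.center_residue: c for c in pfvm.columns}

    def row_chars(rank: int) -> list[str]:
        chars = []
        for pos in range(1, L + 1):
            col = by_center.get(pos)
            if col is None:
                chars.append(" ")
            elif not col.codes:
                chars.append("·" if rank == 1 else " ")
            elif len(col.codes) >= rank:
                chars.append(col.codes[rank - 1][0])
            else:
                chars.append(" ")
        return chars

    rows = [row_chars(r) for r in range(1, depth + 1)]
    blocks = []
    for start in range(0, L, block_width):
        stop = min(start + block_width, L)
        ruler = [" "] * (stop - start)
        for pos in range(start + 1, stop + 1):
            if pos == 1 or pos % 10 == 0:
                label = str(pos)
                offset = pos - start - len(label)
                if offset >= 0:
                    ruler[offset : pos - start] = list(label)
        lines = ["".join(ruler), seq[start:stop]]
        for row in rows:
            segment = row[start:stop]
            if any(ch not in " " for ch in segment):
                lines.append("".join(_styled(ch, color) for ch in segment))
        if profile is not None:
            curve = [" "] * (stop - start)
            for pos in range(start + 1, stop + 1):
                col = by_center.get(pos)
                if col is not None:
                    s = profile.smoothed[col.window_index - 1]
                    curve[pos - start - 1] = str(int(round(s)) % 10)
            lines.append("".join(curve))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
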