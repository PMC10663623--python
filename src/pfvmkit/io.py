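"""Readers and writers for Cα traces (PDB) and sequences (FASTA)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence
from Bio import SeqIO

from .geometry import CATrace

__all__ = [
    "read_ca_trace",
    "read_ca_traces",
    "read_sequence",
    "write_ca_traces",
]


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name.capitalize())
    except Exception:
        return "X"


def read_ca_traces(path: str | Path) -> dict[str, CATrace]:
    """Read the Cα trace of every chain from a PDB file.

    Only ``ATOM`` records of the first model are used; alternate locations
    collapse to the first one.  Residues without a standard three-letter
    name are carried as ``X`` (they encode as unresolved windows).
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    ca = atoms[(atoms.atom_name == "CA") & ~atoms.hetero]
    traces: dict[str, CATrace] = {}
    for chain_id in np.unique(ca.chain_id):
        chain = ca[ca.chain_id == chain_id]
        residues = "".join(_three_to_one(rn) for rn in chain.res_name)
        traces[str(chain_id)] = CATrace(residues, chain.coord)
    if not traces:
        raise ValueError(f"no Cα atoms found in {path}")
    return traces


def read_ca_trace(path: str | Path, chain: str | None = None) -> CATrace:
    """Read one chain's Cα trace (the first chain when none is named)."""
    traces = read_ca_traces(path)
    if chain is None:
        return traces[sorted(traces)[0]]
    if chain not in traces:
        raise ValueError(
            f"chain {chain!r} not in {path} (has {sorted(traces)})"
        )
    return traces[chain]


def _trace_to_atoms(trace: CATrace, chain_id: str = "A") -> struc.AtomArray:
    n = len(trace)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(trace.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.arange(1, n + 1)
    atoms.ins_code = np.full(n, "")
    atoms.res_name = np.array(
        [
            ProteinSequence.convert_letter_1to3(r).upper()
            if r in ProteinSequence._dict_1to3
            else "UNK"
            for r in trace.residues.upper()
        ]
    )
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.set_annotation("occupancy", np.ones(n))
    atoms.set_annotation("b_factor", np.zeros(n))
    return atoms


def write_ca_traces(
    traces: CATrace | Sequence[CATrace], path: str | Path, chain_id: str = "A"
) -> None:
    """Write one trace (single model) or an ensemble (one MODEL each).

    The output is a Cα-only PDB dialect with occupancy 1.00 and B-factor
    0.00; ensemble members must share the same residue sequence.
    """
    if isinstance(traces, CATrace):
        traces = [traces]
    if not traces:
        raise ValueError("no traces to write")
    if len({t.residues for t in traces}) != 1:
        raise ValueError("ensemble members must share one residue sequence")
    pdb = PDBFile()
    if len(traces) == 1:
        pdb.set_structure(_trace_to_atoms(traces[0], chain_id))
    else:
        template = _trace_to_atoms(traces[0], chain_id)
        stack = struc.stack([template] * len(traces))
        stack.coord = np.stack(
            [np.asarray(t.coords, dtype=np.float32) for t in traces]
        )
        pdb.set_structure(stack)
    pdb.write(str(path))


def read_sequence(source: str | Path, name: str | None = None) -> str:
    """Resolve a sequence argument: FASTA file path or raw residue string.

    For FASTA input the first record is used unless ``name`` selects one.
    """
    path = Path(str(source))
    if path.exists() and path.is_file():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {source}")
        if name is None:
            return str(records[0].seq).upper()
        for rec in records:
            if rec.id == name:
                return str(rec.seq).upper()
        raise ValueError(f"record {name!r} not found in {source}")
    seq = str(source).strip().upper()
    if not seq.isalpha():
        raise ValueError(
            "sequence argument is neither an existing file nor a residue string"
        )
    return seq
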