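# pfvmkit

A toolkit for describing protein backbone folding — and its intrinsic
disorder — with a discrete structural alphabet.

Intrinsically disordered proteins (IDPs) and regions (IDRs) do not adopt a
single stable fold; most disorder predictors report *where* a sequence is
flexible but not *which* folds the flexible region can adopt.  `pfvmkit`
implements a folding-fingerprint approach that answers both questions:

* **PFSC** (protein folding shape code): every window of five consecutive
  residues (a *folden*) is reduced to three internal coordinates — the two
  overlapping virtual Cα dihedrals δ₁ (Cα1–Cα4) and δ₂ (Cα2–Cα5) plus the
  Cα1–Cα5 distance κ — each trichotomized into α-like / β-like / other.
  The 3×3×3 cells of this descriptor cube are the 27 folding shapes,
  written with the letters A–Z and `$`.  `A` is the typical α-helix shape,
  `B` the typical β-strand; Y/P/D/H carry partial helix character, E/G/S/M
  partial strand character, V/J mix both, and 15 letters cover irregular
  shapes.  Any Cα trace of length L maps to a gap-free shape string of
  length L − 4, and shape strings map back to 3D Cα traces.
* **Fold lookup library**: the 5-mer → shape mapping tallied over a
  structure collection (the key space is 20⁵ = 3,200,000 possible 5-mers;
  an entry holds at most the 27 codes).
* **PFVM** (protein folding variation matrix): for a query sequence, one
  ranked column of codes per 5-residue window, aligned to the window's
  center residue.  The per-column code count is the local disorder degree,
  its 5-column moving average is the disorder curve, the first-ranked row
  is the single most probable conformation, and substituting letters
  within columns enumerates or samples alternative conformers, which the
  builder converts back into Cα ensembles.

It is aimed at structural bioinformaticians studying IDPs/IDRs, comparing
conformational variability across sequences or mutations, or generating
coarse Cα ensembles from sequence.

## Worked example

The library ships a small curated lookup table covering a handful of
5-mers.  Assembling the matrix for the 8-residue sequence `MEDSQSDM`:

```python
>>> from pfvmkit import *
>>> table = worked_example_table()
>>> pfvm = assemble_pfvm("MEDSQSDM", table)
>>> print(render_text(pfvm), end="")
1
MEDSQSDM
  APAA
  DAEE
   DVR
   V V
     B
     S
     W
     Y
```

The four columns sit under the center residues of the windows `MEDSQ`,
`EDSQS`, `DSQSD` and `SQSDM`.  The first window has only the two
helix-class shapes A and D — locally rigid, helix-forming — while `SQSDM`
has eight shapes spanning helix, strand and irregular folds: a locally
disordered window.  Numerically:

```python
>>> top_string(pfvm)
'APAA'
>>> column_counts(pfvm).tolist()      # disorder degree D per column
[2, 4, 3, 8]
>>> disorder_profile(pfvm).smoothed   # 5-column moving average S
array([3.  , 4.25, 4.25, 5.  ])
>>> ss_tendency(pfvm)
['helix', 'helix', 'ambiguous', 'ambiguous']
```

`enumerate_strings(pfvm, mode="substitute_one")` yields the top string
plus all 13 single-column replacements (14 strings), and
`build_ca_trace("APAA", "MEDSQSDM")` realizes any of them as an 8-residue
Cα trace with 3.8 Å virtual bonds, ready for
`ensemble_spread` (pairwise superposed RMSD) or `write_ca_traces`
(multi-model Cα-only PDB).

The same workflows are available from the shell:

```sh
pfvm fixtures worked-table -o lib.tsv
pfvm matrix MEDSQSDM --lib lib.tsv --text
pfvm disorder MEDSQSDM --lib lib.tsv --window 5
pfvm conformers MEDSQSDM --lib lib.tsv --mode sample -k 5 --seed 7 -o out.pdb
```

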