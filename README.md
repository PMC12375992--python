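# hydrophobins

Sequence and structure analysis of fungal **hydrophobins** — small secreted
proteins that self-assemble into amphipathic films at hydrophobic–hydrophilic
interfaces (fungal spore coats, aerial hyphae, biomaterial coatings).

Hydrophobins are defined by a conserved motif of eight cysteines,

```
C – Xa – C C – Xb – C – Xc – C – Xd – C C – Xe – C
```

with adjacent doublets at ordinals 2–3 and 6–7, forming four disulfide bonds
(canonical topology C1–C6, C2–C5, C3–C4, C7–C8) that staple a small β-barrel
core. The residues between numbered cysteines are the intercysteine loops
(C1–C2 … C7–C8); the hydrophobic C7–C8 loop carries the aggregation segment
of class I hydrophobins (FLIIN in EAS of *Neurospora crassa*). Class I and
class II differ in solubility, hydropathy, and — the handle used here —
intercysteine spacing.

The package provides, as a library plus a `hydrophobins` CLI:

- **seqio** — FASTA I/O (UniProt-style headers), validation, trimming of
  residues before the first cysteine (the β-barrel boundary).
- **physchem** — length, Cys count, residue composition, GRAVY
  (Kyte–Doolittle mean hydropathy) and isoelectric point (Bjellqvist pK set,
  Henderson–Hasselbalch charge, bisection).
- **cysmotif** — motif scanning (octet and 10-Cys decet), nearest-centroid
  class I/II classification on the 7-component spacing vector, and mining of
  non-canonical features: 10-cysteine five-disulfide candidates (< 250 aa),
  extended N-terminal tails (≥ 70 aa before the first Cys), and
  polyhydrophobins (several motifs per chain).
- **structio** — PDB parsing (multi-model ensembles, pLDDT in the B-factor
  column), disulfide detection from Sγ–Sγ distances with topology mapping
  against the canonical pattern, Shrake–Rupley SASA (Bondi radii, 1.4 Å
  probe).
- **structcompare** — model-quality assessment: Cα RMSD after Kabsch
  superposition, TM-score (d0(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å,
  reference-normalised, maximised by iterative fragment seeding), and
  superposition-free lDDT-Cα (tolerances 0.5/1/2/4 Å within 15 Å). Quality
  cut-offs: RMSD < 2.5 Å, lDDT-Cα > 0.6, TM-score > 0.6. Against NMR
  ensembles the member with lowest Cα RMSD is reported.
- **cladetree** — all-vs-all 1 − TM distances, UPGMA tree with Newick
  output, and k-clade assignment by ultrametric cut.
- **synthdata** — seeded generators for motif-bearing sequences (with
  planted non-canonical variants and recorded ground truth) and structure
  pairs (coiled Cα template + Gaussian noise + rigid motion), so the whole
  pipeline runs without any database access.

## Worked example

```python
from hydrophobins import seqio, physchem, cysmotif

eas = ("SATTIGPNTCSIDDYKPYCCQSMSGSASLGCVVGVIGSQCGASVKCC"
       "KDDVTNTGNSFLIINAANCVA")  # EAS Δ15, class I, N. crassa
rec = seqio.SequenceRecord(id="EAS_D15", residues=eas)
motifs = cysmotif.scan_cys_motif(rec)
m = motifs[0]
print(f"cysteines at {m.cys_positions}")
print(f"spacing     {m.spacing}")
print(f"doublets    {sorted(m.doublet_ordinals)}")
loop = m.loops["C7-C8"]
print(f"C7-C8 loop  {loop.start}-{loop.end}: {loop.sequence}")
print(f"GRAVY       {physchem.gravy(rec.residues):.3f}")
print(f"pI          {physchem.isoelectric_point(rec.residues):.2f}")
cls = cysmotif.classify_sequence(rec, motifs)
print(f"class       {cls.label} (margin {cls.confidence:.2f})")
```

prints

```
cysteines at (10, 19, 20, 31, 40, 46, 47, 66)
spacing     (8, 0, 10, 8, 5, 0, 18)
doublets    [(2, 3), (6, 7)]
C7-C8 loop  48-65: KDDVTNTGNSFLIINAAN
GRAVY       0.313
pI          4.58
class       class_I (margin 1.45)
```

One octet motif: the cysteine doublets sit at ordinals (2,3) and (6,7), the
C7–C8 loop (residues 48–65) contains the FLIIN aggregation segment, the
positive GRAVY and acidic pI are typical of hydrophobins, and the spacing
vector lands nearest the class I centroid.

The same stages run from the shell:

```bash
hydrophobins simulate --n 100 --n-ten-cys 10 --n-extended-tail 10 --n-poly 5 \
    --seed 1 --out-dir syn
hydrophobins all syn/synthetic_sequences.fasta --out-dir out
hydrophobins bench pairs.tsv         # pair_id / predicted / experimental / class_label
hydrophobins tree model1.pdb model2.pdb ... --k 6
```

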