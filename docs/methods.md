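# Methods

This note documents the models, parameters, and numerical choices behind
the package, and what the synthetic-data tests do and do not establish
about real data.

## Sequence model and motif scan

A sequence record holds uppercase one-letter residues (20 standard codes
plus X/B/Z/U; gaps are stripped on read). Selenocysteine (U) is never
counted as cysteine: the motif definitions concern literal Cys. Trimming
removes everything before the first cysteine, which marks the boundary of
the disulfide-stapled β-barrel core; trimming is idempotent and records the
number of residues removed. Records without any cysteine raise an explicit
no-cysteine signal and are excluded from motif analyses.

The canonical motif is an octet of cysteines with doublets at ordinals
(2,3) and (6,7). The scanner walks the cysteine positions left to right;
at each unconsumed cysteine the window of the next eight cysteines is
tested against the spacing template — doublet gaps exactly 0, singlet gaps
within configurable bounds — and a match consumes the window. Greedy
non-overlapping matching makes polyhydrophobin segmentation deterministic.
Default singlet bounds are 1–75 residues: wide enough for the longest
loops in solved structures, tight enough not to bridge two domains of a
polyhydrophobin. **Decet mode** (10 cysteines) accepts any window of ten
cysteines whose nonzero gaps are within the singlet bounds and which
contains at least two doublets; known 10-Cys hydrophobins insert their
extra disulfide pair at varying positions near the canonical doublets, so
a positional rather than fixed template is used. Ordinals are always
sequence-positional (C1…C10), so topology comparisons are well defined
even when the naming of bonds shifts between the octet and decet.

## Class I / class II classification

No published numeric spacing criterion separates the classes, so the
classifier is an explicitly heuristic nearest-centroid rule on the
7-component intercysteine spacing vector (Euclidean distance to per-class
centroids shipped as a JSON config and regenerable from any labelled set
with `compute_centroids`). Confidence is the margin between the two
centroid distances; exact ties are broken by the mean Kyte–Doolittle
hydropathy of the C7–C8 loop (more hydrophobic → class I, since that loop
carries the class I aggregation segment). Sequences without a motif are
labelled `not_hydrophobin` rather than raising. The shipped centroids are
(7, 0, 22, 12, 7, 0, 14) for class I and (10, 0, 11, 16, 8, 0, 6) for
class II — package parameters consistent with solved representatives
(EAS-like vs HFBII-like), not measured corpus values.

## Non-canonical feature mining

Three flags, with thresholds fixed by the analysis design:

- **five-disulfide candidate**: exactly 10 cysteines in a chain < 250
  residues (compact enough to be a single domain with a putative fifth
  bond);
- **extended N-tail**: ≥ 70 residues before the first cysteine (canonical
  hydrophobins carry a 15–25 residue signal peptide plus < 25 disordered
  residues, so 70 is far outside the normal range);
- **polyhydrophobin**: ≥ 2 non-overlapping motifs in a chain > 250
  residues, labelled di/tri/tetra/penta by domain count.

## Physicochemical profile

GRAVY is the arithmetic mean of 1982 Kyte–Doolittle values; ambiguous
codes (X/B/Z) and U are excluded from the mean rather than imputed — a
conservative choice that never fabricates hydropathy. The isoelectric
point solves net charge = 0 under the Henderson–Hasselbalch model with the
Bjellqvist pK set, including residue-specific N-terminal pK values; all
cysteines are treated as free thiols (sequence-only prediction; disulfide
state is deliberately ignored). Bisection runs to an interval width of
1e-7 pH: the charge curve can be nearly flat around pI for sequences with
few ionizable groups, so converging on the interval (not merely on
|charge| < 1e-3) is required for the result to pin the zero crossing; the
|charge| < 1e-3 contract is still asserted. The tests cross-check both
quantities against Biopython's independent implementations and against a
brute-force pH grid at 1e-4 resolution.

## Structure I/O, disulfides, SASA

PDB files are parsed with gemmi; one `StructureModel` per MODEL block,
author residue numbering retained, alternate locations resolved by blank
altloc first, then highest occupancy, ties toward 'A'. The temperature
factor is stored as per-residue confidence (pLDDT for predicted models).
Correspondence between structures is by sequence, never by residue
numbering.

Disulfides are detected by greedy minimum-distance matching of cysteine
Sγ pairs under a 2.5 Å cutoff (a covalent S–S bond is ≈ 2.05 Å; 2.5 Å
excludes non-bonded contacts). Candidate pairs are sorted by (distance,
lower ordinal), which makes the matching deterministic and independent of
atom order. Unpaired cysteines are reported as free. Bonds are ordinal
pairs; `canonical_match` is true iff the set equals
{C1–C6, C2–C5, C3–C4, C7–C8}. For non-canonical sets a spatial
correspondence to a canonical reference is computed by Cα superposition
followed by greedy nearest-midpoint assignment of bonds, which lets a
shifted connectivity (e.g. the canonical C1–C6 appearing at the C4–C7
sequence position of a 10-Cys protein) be read off directly.

SASA uses Shrake–Rupley quadrature: each heavy atom's sphere (Bondi radius
plus 1.4 Å probe) is sampled at 960 quasi-uniform golden-spiral points;
points inside any neighbouring expanded sphere are occluded. Exactly
coincident duplicate atoms are counted once. Halving the point count
changes totals by < 2% on fixture structures. Absolute SASA values on
as-given (un-relaxed, possibly Cα-only) coordinates are lower bounds and
are not comparable across preprocessing pipelines; the package warns when
a model lacks heavy-atom detail.

## Model-quality metrics

- **Kabsch / Cα RMSD**: SVD solution with determinant correction (proper
  rotations only); < 3 points or collinear references raise a degenerate-
  input error. Verified against a brute-force Euler-grid rotation search.
- **TM-score**: TM = (1/L_ref) Σ 1/(1 + (d_i/d0)²) with
  d0 = 1.24·(L_ref − 15)^⅓ − 1.8, floored at 0.5 Å (hydrophobins are
  short, ~70–120 aa). Normalisation is by the reference (experimental)
  chain length. The score is maximised by seeding superpositions from the
  full chain and contiguous fragments of length L/2 and L/4 at half-length
  strides, each refined by re-superposing on residues with d_i <
  max(d0, 4.5 Å) until the inlier set stabilises (≤ 30 iterations); the
  best score over seeds is reported.
- **lDDT-Cα**: superposition-free; reference Cα–Cα distances < 15 Å
  (i ≠ j), preserved at tolerance t if |d_model − d_ref| < t, averaged
  over t ∈ {0.5, 1, 2, 4} Å. No stereochemistry penalty; Cα only.

Residue pairing uses index pairing for identical sequences, otherwise a
global alignment (match +1, mismatch −1, gap −2) restricted to aligned
non-gap pairs with Cα present in both partners. Against an ensemble, all
metrics are computed per member and the member minimising Cα RMSD is
chosen. Quality flags apply the standard cut-offs (RMSD < 2.5 Å,
lDDT-Cα > 0.6, TM > 0.6).

## Distance matrix, UPGMA, clades

Pairwise distance is 1 − TM with TM averaged over both normalisation
directions — symmetric, bounded in [0,1], length-aware. UPGMA
(average-linkage) gives an ultrametric tree; node heights are half the
merge distance. Labels are sorted lexicographically before clustering so
tied merges resolve identically regardless of input order, and Newick
children are ordered by smallest leaf label, giving a canonical text form.
The k-clade assignment applies the first (n − k) merges — equivalent to
cutting just below the (n − k + 1)-th merge height, with ties resolving to
the lower height — so finer cuts always refine coarser ones. k is a user
parameter (default 6 in the pipeline, matching the number of main clades
the full-corpus structure dendrogram resolves into); nothing in the method
discovers k.

## Synthetic data: what it emulates, and what it does not

The sequence generator assembles
`[N-tail][C + loops drawn per class spacing][C-tail]` with residues drawn
by largest-remainder quota from class-specific frequency tables, so every
sequence is compositionally faithful to its class profile (GRAVY
concentrated in 0–1, pI clustered near 4–6, acidic overall). Class spacing
draws are Gaussian (rounded, clamped ≥ 1) with means at the shipped
centroids and SDs of (1.5, 0, 3.5, 2.5, 1.5, 0, 3) / (1, 0, 1.5, 2, 1, 0,
1.5) for class I / II — deliberately well-separated, which is the regime
the nearest-centroid round-trip property assumes. Planted variants (10-Cys
with the extra doublet inside the C-terminal loop; tails of 70–120
residues; 3–5 concatenated domains with Gly/Asp-rich linkers, padded past
250 residues) are disjoint subsets recorded in a ground-truth table. The
default corpus mixes classes 79/21, echoing the curated corpus proportions.

The structure generator uses a Cα helix template with the per-turn rise
solved from the radius so consecutive Cα sit exactly 3.8 Å apart, bent
along a large-radius arc (a near-isometry) so superpositions are fully
constrained; perturbed copies add isotropic Gaussian noise and a uniform
random rotation plus translation. Families for clade tests differ in helix
radius, handedness, and bend.

Passing the synthetic suites therefore establishes: the filters implement
their thresholds exactly; the classifier recovers well-separated classes;
the metrics respond monotonically to coordinate noise and are invariant
under rigid motion; and the distance→tree→cut path recovers planted
structure families. It does **not** establish: classification accuracy on
real (overlapping) class distributions, absolute SASA or metric values on
real all-atom structures, or robustness to sequencing/annotation noise —
real hydrophobin corpora are messier than any of these generators.

## Problem sizes and determinism

All simulations run at desk scale: 100-sequence corpora, 60–70 residue
Cα traces, 10–20 replicates per noise level, 12-structure clade sets —
sizes at which every statistical check is stable across seeds while the
whole suite runs in well under a minute. One integer seed drives each
generator through a single `numpy.random.Generator`; identical
spec + seed yields byte-identical FASTA/PDB/TSV output, and the pipeline
writes a manifest (config, seed, package version) alongside its reports.

## Known limitations

- The class I/II classifier is a package heuristic; curated family
  annotation remains the ground truth on real data.
- The decet template is positional and permissive; rare 10-Cys
  arrangements with fewer than two doublets would be missed by the scan
  (though still flagged by the cysteine-count filter).
- The benchmark against published per-class metric means requires the
  original experimental/predicted coordinate files, which cannot be
  redistributed; the corresponding tests state how to supply them.
- lDDT is Cα-only by design; no all-atom or stereochemistry-aware variant
  is provided.
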