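"""Seeded synthetic hydrophobin sequences and structure pairs.

The generators emulate the statistical structure the analysis modules
assume, with recorded ground truth, so the whole pipeline is testable
without any database access:

- sequences carry the canonical eight-cysteine motif (doublets at ordinals
  2-3 and 6-7) with class-specific intercysteine spacing drawn from
  Gaussian gap distributions, plus planted non-canonical variants:
  10-cysteine sequences (< 250 residues), extended N-terminal tails
  (>= 70 residues before the first Cys), and polyhydrophobins
  (3-5 concatenated domains on a > 250 residue chain);
- structure pairs are a template Calpha trace (a coiled helix with 3.8 A
  consecutive spacing, so local distances look protein-like) plus isotropic
  Gaussian coordinate noise and an optional random rigid motion, emulating
  predicted-vs-experimental model pairs.

All randomness flows from one integer seed through a single
``numpy.random.Generator``, making outputs byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .seqio import SequenceRecord
from .structio import StructureModel, build_model, write_pdb

# Class-specific intercysteine gap distributions (residue counts between
# consecutive cysteines; doublet gaps fixed at 0). These are artifact
# parameters chosen to echo the spacing of solved class I (EAS-like) and
# class II (HFBII-like) hydrophobins: class I has a long C3-C4 loop and
# long C7-C8 loop, class II is compact and tightly conserved.
CLASS_SPACING_MEANS = {
    "class_I": (7.0, 0.0, 22.0, 12.0, 7.0, 0.0, 14.0),
    "class_II": (10.0, 0.0, 11.0, 16.0, 8.0, 0.0, 6.0),
}
CLASS_SPACING_SDS = {
    "class_I": (1.5, 0.0, 3.5, 2.5, 1.5, 0.0, 3.0),
    "class_II": (1.0, 0.0, 1.5, 2.0, 1.0, 0.0, 1.5),
}

# Loop/tail residue frequencies (cysteine inserted explicitly, never drawn).
# Tuned for a hydrophobin-like profile: GRAVY between 0 and 1, acidic pI
# (D+E outweigh K+R+H), rich in small/hydrophobic residues.
_AA = "ADEFGHIKLMNPQRSTVWY"
_FREQ = {
    "class_I": np.array(
        [0.1225, 0.05, 0.035, 0.03, 0.105, 0.01, 0.07, 0.03, 0.08, 0.01,
         0.04, 0.04, 0.03, 0.015, 0.1125, 0.08, 0.12, 0.005, 0.015]
    ),
    "class_II": np.array(
        [0.115, 0.05, 0.035, 0.03, 0.095, 0.01, 0.06, 0.03, 0.10, 0.01,
         0.04, 0.05, 0.03, 0.015, 0.11, 0.08, 0.12, 0.005, 0.015]
    ),
}


@dataclass(frozen=True)
class SequenceGenSpec:
    """Study-conditions recipe for the sequence generator.

    Defaults emulate the curated corpus: a ~79/21 class I / class II mix
    (the real corpus is 5414 vs 1442 sequences), canonical N-tails of 5-30
    residues, and explicitly planted non-canonical subsets.
    """

    n: int = 100
    class_i_fraction: float = 0.79
    n_ten_cys: int = 0
    n_extended_tail: int = 0
    n_polyhydrophobin: int = 0
    poly_domain_count: int = 3
    extended_tail_range: tuple[int, int] = (70, 120)
    canonical_tail_range: tuple[int, int] = (5, 30)
    c_tail_range: tuple[int, int] = (2, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_ten_cys + self.n_extended_tail + self.n_polyhydrophobin
        if planted > self.n:
            raise ValueError("more planted variants than sequences requested")
        if not 2 <= self.poly_domain_count <= 5:
            raise ValueError("polyhydrophobin domain count must be 2..5")


def _draw_residues(rng: np.random.Generator, n: int, label: str) -> str:
    """Draw ``n`` residues with class-typical composition.

    Residue counts follow the class frequency table by largest-remainder
    quota (so every segment — and hence every sequence — is compositionally
    faithful, as the real corpus is), then the segment is shuffled.
    """
    if n == 0:
        return ""
    freq = _FREQ[label] / _FREQ[label].sum()
    ideal = freq * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    if short > 0:
        # distribute the remainder stochastically, weighted by what's owed
        rem = ideal - counts
        extra = rng.choice(len(freq), size=short, replace=False, p=rem / rem.sum())
        counts[extra] += 1
    pool = np.repeat(list(_AA), counts)
    rng.shuffle(pool)
    return "".join(pool)


def _draw_spacing(rng: np.random.Generator, label: str) -> list[int]:
    means, sds = CLASS_SPACING_MEANS[label], CLASS_SPACING_SDS[label]
    gaps = []
    for m, s in zip(means, sds):
        if s == 0:
            gaps.append(int(m))
        else:
            gaps.append(max(1, int(round(rng.normal(m, s)))))
    return gaps


def _core_domain(rng: np.random.Generator, label: str, gaps: Sequence[int]) -> str:
    parts = ["C"]
    for g in gaps:
        parts.append(_draw_residues(rng, g, label))
        parts.append("C")
    return "".join(parts)


def _ten_cys_gaps(rng: np.random.Generator, label: str) -> list[int]:
    """Decet spacing: canonical octet with an extra adjacent pair inserted
    into the long C-terminal loop, echoing known 10-Cys hydrophobins."""
    gaps = _draw_spacing(rng, label)
    last = gaps[-1]
    a = max(1, last // 2)
    b = max(1, last - a)
    return gaps[:-1] + [a, 0, b]


def synth_sequences(
    spec: SequenceGenSpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate sequences plus a ground-truth table.

    The planted subsets (10-Cys, extended tail, polyhydrophobin) are
    disjoint; the remaining sequences are canonical single-domain
    hydrophobins. Ground truth records the class, planted flags, tail
    length, and cysteine positions of every sequence.
    """
    rng = np.random.default_rng(spec.seed)
    kinds = (
        ["ten_cys"] * spec.n_ten_cys
        + ["extended_tail"] * spec.n_extended_tail
        + ["polyhydrophobin"] * spec.n_polyhydrophobin
    )
    kinds += ["canonical"] * (spec.n - len(kinds))
    rng.shuffle(kinds)

    records, truth = [], []
    for i, kind in enumerate(kinds):
        label = "class_I" if rng.random() < spec.class_i_fraction else "class_II"
        tail_range = (
            spec.extended_tail_range if kind == "extended_tail" else spec.canonical_tail_range
        )
        ntail = int(rng.integers(tail_range[0], tail_range[1] + 1))
        ctail = int(rng.integers(spec.c_tail_range[0], spec.c_tail_range[1] + 1))

        if kind == "ten_cys":
            core = _core_domain(rng, label, _ten_cys_gaps(rng, label))
            body = core
        elif kind == "polyhydrophobin":
            domains = [
                _core_domain(rng, label, _draw_spacing(rng, label))
                for _ in range(spec.poly_domain_count)
            ]
            # Gly/Asp-rich linkers, as in natural tri-/pentahydrophobins
            linker_aas = list("GDGS")
            linkers = [
                "".join(rng.choice(linker_aas, size=int(rng.integers(10, 21))))
                for _ in range(spec.poly_domain_count - 1)
            ]
            body = domains[0]
            for lk, dom in zip(linkers, domains[1:]):
                body += lk + dom
            # a polyhydrophobin chain must exceed the single-domain length cap
            while ntail + len(body) + ctail <= 250:
                body += _draw_residues(rng, 20, label)
        else:
            body = _core_domain(rng, label, _draw_spacing(rng, label))
            if kind == "canonical" and ntail + len(body) + ctail >= 250:
                ctail = 2  # keep canonical singletons compact

        seq = _draw_residues(rng, ntail, label) + body + _draw_residues(rng, ctail, label)
        rec = SequenceRecord(
            id=f"SYN{i:04d}", residues=seq, description=f"synthetic {kind}",
            class_label=label,
        )
        records.append(rec)
        truth.append(
            {
                "seq_id": rec.id,
                "class_label": label,
                "kind": kind,
                "ten_cys": kind == "ten_cys",
                "extended_tail": kind == "extended_tail",
                "polyhydrophobin": kind == "polyhydrophobin",
                "n_tail_length": ntail,
                "length": len(seq),
                "cys_positions": ";".join(
                    str(p + 1) for p, c in enumerate(seq) if c == "C"
                ),
            }
        )
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureGenSpec:
    """Recipe for one template-plus-perturbation structure pair."""

    n_residues: int = 70
    noise_sd: float = 1.0  # A, isotropic per coordinate
    apply_rigid_motion: bool = True
    n_models: int = 1
    curvature: float = 0.015  # slow arc bend superimposed on the helix
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_residues < 10:
            raise ValueError("template needs at least 10 residues")


def helix_template(
    n_residues: int,
    curvature: float = 0.015,
    radius: float = 2.3,
    handedness: int = 1,
) -> np.ndarray:
    """Calpha trace of a gently bent helix with ~3.8 A consecutive spacing.

    The per-turn rise is solved from the radius so consecutive Calpha
    atoms sit 3.8 A apart on the straight helix; a slow arc bend of radius
    1/curvature (a near-isometry for radius << 1/curvature) then turns the
    rod into a coiled curve so superpositions are fully constrained.
    """
    if not 0.0 < radius < 2.48:
        raise ValueError("radius must be in (0, 2.48) A to allow 3.8 A spacing")
    i = np.arange(n_residues)
    theta = handedness * np.deg2rad(100.0) * i
    chord_xy = 2.0 * radius * np.sin(np.deg2rad(50.0))
    rise = np.sqrt(3.8**2 - chord_xy**2)
    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    z = rise * i
    if curvature <= 0:
        return np.column_stack((x, y, z))
    big_r = 1.0 / curvature
    return np.column_stack(
        ((big_r + x) * np.sin(z / big_r), y, (big_r + x) * np.cos(z / big_r) - big_r)
    )


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random proper rotation plus a translation in [-20, 20]^3 A."""
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    return rot, trans


def synth_structure_pair(
    spec: StructureGenSpec,
) -> tuple[StructureModel, list[StructureModel]]:
    """(reference template, perturbed copies) related by noise + rigid motion.

    Each perturbed model is the template plus N(0, noise_sd^2) per
    coordinate, then (optionally) a random rotation and translation —
    emulating a predicted model vs an experimental structure/ensemble.
    """
    rng = np.random.default_rng(spec.seed)
    template = helix_template(spec.n_residues, spec.curvature)
    reference = build_model(template, model_index=1)
    perturbed = []
    for m in range(spec.n_models):
        coords = template + rng.normal(0.0, spec.noise_sd, size=template.shape)
        if spec.apply_rigid_motion:
            rot, trans = random_rigid_motion(rng)
            coords = coords @ rot.T + trans
        perturbed.append(build_model(coords, model_index=m + 1))
    return reference, perturbed


def synth_structure_families(
    n_families: int = 3,
    members_per_family: int = 4,
    noise_sd: float = 0.5,
    n_residues: int = 60,
    seed: int = 0,
) -> tuple[dict[str, StructureModel], dict[str, int]]:
    """Labelled structures drawn from distinct template folds.

    Family templates differ in helix radius, handedness, and bend so
    between-family TM is low; members add small within-family noise plus a
    rigid motion. Returns (label -> model, label -> family index) for
    clade-recovery checks.
    """
    rng = np.random.default_rng(seed)
    params = [
        {"radius": 2.3, "handedness": 1, "curvature": 0.010},
        {"radius": 1.2, "handedness": 1, "curvature": 0.022},
        {"radius": 2.3, "handedness": -1, "curvature": 0.016},
        {"radius": 1.7, "handedness": -1, "curvature": 0.008},
        {"radius": 0.8, "handedness": 1, "curvature": 0.018},
        {"radius": 2.0, "handedness": 1, "curvature": 0.028},
    ]
    if n_families > len(params):
        raise ValueError(f"at most {len(params)} distinct families supported")
    models: dict[str, StructureModel] = {}
    truth: dict[str, int] = {}
    for f in range(n_families):
        template = helix_template(n_residues, **params[f])
        for m in range(members_per_family):
            coords = template + rng.normal(0.0, noise_sd, size=template.shape)
            rot, trans = random_rigid_motion(rng)
            coords = coords @ rot.T + trans
            label = f"F{f}_M{m}"
            models[label] = build_model(coords)
            truth[label] = f
    return models, truth


def synth_disulfide_structure(
    topology: Sequence[tuple[int, int]] = ((1, 6), (2, 5), (3, 4), (7, 8)),
    n_residues: int = 68,
    bond_length: float = 2.04,
) -> StructureModel:
    """Synthetic Calpha trace with cysteine Sgamma pairs realising a given
    disulfide topology.

    Cysteines are placed at EAS-like positions along a helix template; the
    Sgamma atoms of each bonded ordinal pair sit ``bond_length`` apart at a
    site well separated from every other pair, so distance-based detection
    recovers exactly the requested topology. Purely synthetic geometry —
    a stand-in for an experimental disulfide-bonded structure.
    """
    ca = helix_template(n_residues)
    n_cys = max(max(p) for p in topology)
    # EAS-like octet positions, extended with two mid-loop sites for decets
    cys_idx = sorted(p - 1 for p in [10, 19, 20, 31, 40, 46, 47, 66, 52, 58][:n_cys])
    seq = "".join("C" if i in cys_idx else "A" for i in range(n_residues))

    sg: dict[int, np.ndarray] = {}
    for k, (i, j) in enumerate(sorted(topology)):
        centre = np.array([40.0 + 10.0 * k, 15.0, -10.0])
        offset = np.array([bond_length / 2.0, 0.0, 0.0])
        sg[cys_idx[i - 1]] = centre - offset
        sg[cys_idx[j - 1]] = centre + offset
    return build_model(ca, sequence=seq, sg_coords=sg)


def write_synthetic_corpus(
    out_dir: str | Path, spec: SequenceGenSpec
) -> tuple[Path, Path]:
    """Write FASTA + ground-truth TSV; returns the two paths."""
    from .seqio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = synth_sequences(spec)
    fasta = out / "synthetic_sequences.fasta"
    with fasta.open("w") as fh:
        write_fasta(records, fh)
    tsv = out / "synthetic_ground_truth.tsv"
    truth.to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def write_structure_pair(
    out_dir: str | Path, spec: StructureGenSpec
) -> tuple[Path, Path]:
    """Write reference and perturbed ensemble as PDB files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, perturbed = synth_structure_pair(spec)
    ref_path = out / "reference.pdb"
    mod_path = out / "perturbed.pdb"
    write_pdb([reference], ref_path)
    write_pdb(perturbed, mod_path)
    return ref_path, mod_path
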