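"""Hydrophobin cysteine-motif detection, classification, and feature mining.

The canonical hydrophobin motif is an octet of cysteines,

    C - Xa - C C - Xb - C - Xc - C - Xd - C C - Xe - C

with adjacent doublets at ordinals (2,3) and (6,7). The residues between
consecutive numbered cysteines form the named intercysteine loops (C1-C2,
C3-C4, ..., C7-C8); the hydrophobic C7-C8 loop carries the aggregation
segment of class I hydrophobins (FLIIN in EAS). Class I and class II
differ in their intercysteine spacing patterns, which drives the
nearest-centroid classifier here. Mining flags three non-canonical
features: 10-cysteine sequences short enough to be single domains
(five-disulfide candidates), extended disordered N-terminal tails (>= 70
residues before the first Cys), and polyhydrophobins (several motifs in
one chain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import physchem
from .seqio import SequenceRecord

#: canonical doublets: ordinal pairs that are adjacent in sequence
OCTET_DOUBLETS = ((2, 3), (6, 7))

#: thresholds for non-canonical feature mining
TEN_CYS_COUNT = 10
TEN_CYS_MAX_LENGTH = 250
EXTENDED_TAIL_MIN = 70
POLY_MIN_LENGTH = 250

_POLY_LABELS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta"}

NOT_HYDROPHOBIN = "not_hydrophobin"


@dataclass(frozen=True)
class SpacingBounds:
    """Allowed residue counts between consecutive cysteines of the motif.

    Singlet segments (the named loops) accept ``min_gap``..``max_gap``
    residues; doublet segments are fixed at zero (adjacent cysteines).
    The 1-75 default accommodates the longest loops seen in solved
    hydrophobin structures while preventing matches that bridge domains.
    """

    min_gap: int = 1
    max_gap: int = 75


@dataclass(frozen=True)
class Loop:
    """One intercysteine loop: residues strictly between two cysteines."""

    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    sequence: str


@dataclass(frozen=True)
class CysMotif:
    """Positions and loop decomposition of one cysteine octet (or decet)."""

    cys_positions: tuple[int, ...]  # 1-based residue indices
    spacing: tuple[int, ...]  # residues between consecutive cysteines
    loops: Mapping[str, Loop]
    doublet_ordinals: frozenset[tuple[int, int]]

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)

    @property
    def cys_ordinals(self) -> tuple[str, ...]:
        return tuple(f"C{i}" for i in range(1, self.n_cys + 1))

    @property
    def span(self) -> tuple[int, int]:
        return self.cys_positions[0], self.cys_positions[-1]


@dataclass(frozen=True)
class MiningReport:
    """Non-canonical feature flags for one sequence."""

    seq_id: str
    motif_found: bool
    five_disulfide_candidate: bool
    extended_ntail: bool
    n_tail_length: int
    polyhydrophobin: bool
    domain_count: int
    domain_label: str


def _build_motif(seq: str, positions: Sequence[int]) -> CysMotif:
    """Assemble a CysMotif from 1-based cysteine positions."""
    spacing = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    loops: dict[str, Loop] = {}
    doublets = []
    for i, gap in enumerate(spacing):
        lo, hi = positions[i], positions[i + 1]
        if gap == 0:
            doublets.append((i + 1, i + 2))
        else:
            loops[f"C{i + 1}-C{i + 2}"] = Loop(
                start=lo + 1, end=hi - 1, sequence=seq[lo : hi - 1]
            )
    return CysMotif(
        cys_positions=tuple(positions),
        spacing=spacing,
        loops=loops,
        doublet_ordinals=frozenset(doublets),
    )


def _octet_window_ok(gaps: Sequence[int], bounds: SpacingBounds) -> bool:
    """Check the 7 consecutive gaps of an 8-Cys window against the template."""
    doublet_idx = {1, 5}  # gaps after ordinals 2 and 6 (0-based gap index)
    for i, g in enumerate(gaps):
        if i in doublet_idx:
            if g != 0:
                return False
        elif not (bounds.min_gap <= g <= bounds.max_gap):
            return False
    return True


def _decet_window_ok(gaps: Sequence[int], bounds: SpacingBounds) -> bool:
    """10-Cys variant: every gap either zero (doublet) or within singlet
    bounds, with at least two doublets. The extra disulfide pair of known
    10-Cys hydrophobins inserts near the canonical doublets, but its exact
    position varies, so the template is positional rather than fixed."""
    n_doublets = sum(1 for g in gaps if g == 0)
    if n_doublets < 2:
        return False
    return all(g == 0 or bounds.min_gap <= g <= bounds.max_gap for g in gaps)


def scan_cys_motif(
    record: SequenceRecord,
    bounds: SpacingBounds | None = None,
    decet: bool = False,
) -> list[CysMotif]:
    """Find every non-overlapping cysteine octet (or decet) in the sequence.

    A greedy left-to-right scan over the cysteine positions: at each
    unconsumed cysteine, the window of the next 8 (or 10) cysteines is
    tested against the spacing template; on a match the whole window is
    consumed. Greedy non-overlapping matching makes polyhydrophobin
    segmentation deterministic. Selenocysteine (U) is never counted as
    cysteine. Returns an empty list when no motif is present.
    """
    bounds = bounds or SpacingBounds()
    seq = record.residues
    cys = [i + 1 for i, c in enumerate(seq) if c == "C"]
    size = 10 if decet else 8
    check = _decet_window_ok if decet else _octet_window_ok

    motifs: list[CysMotif] = []
    i = 0
    while i + size <= len(cys):
        window = cys[i : i + size]
        gaps = [window[j + 1] - window[j] - 1 for j in range(size - 1)]
        if check(gaps, bounds):
            motifs.append(_build_motif(seq, window))
            i += size
        else:
            i += 1
    return motifs


# ---------------------------------------------------------------------------
# class I / class II nearest-centroid classifier
# ---------------------------------------------------------------------------


def load_default_centroids() -> dict[str, np.ndarray]:
    """Spacing centroids shipped with the package (regenerable from any
    labelled set via :func:`compute_centroids`)."""
    text = resources.files("hydrophobins").joinpath("data/class_centroids.json").read_text()
    raw = json.loads(text)
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def compute_centroids(
    records: Iterable[SequenceRecord], bounds: SpacingBounds | None = None
) -> dict[str, np.ndarray]:
    """Mean spacing vector per class over records with a labelled octet motif."""
    acc: dict[str, list[np.ndarray]] = {}
    for rec in records:
        if rec.class_label not in ("class_I", "class_II"):
            continue
        motifs = scan_cys_motif(rec, bounds)
        if motifs:
            acc.setdefault(rec.class_label, []).append(
                np.asarray(motifs[0].spacing, dtype=float)
            )
    if not acc:
        raise ValueError("no labelled records with a detectable motif")
    return {label: np.mean(np.stack(vecs), axis=0) for label, vecs in acc.items()}


@dataclass(frozen=True)
class Classification:
    seq_id: str
    label: str
    confidence: float


def classify_sequence(
    record: SequenceRecord,
    motifs: Sequence[CysMotif],
    centroids: Mapping[str, np.ndarray] | None = None,
) -> Classification:
    """Assign class I / class II by nearest spacing centroid.

    The 7-component intercysteine spacing vector of the first motif is
    compared (Euclidean) to each class centroid; confidence is the margin
    between the two distances. Exact ties are broken by the mean hydropathy
    of the C7-C8 loop: the more hydrophobic loop (the class I aggregation
    segment) votes class I. Sequences without a motif are labelled
    not-a-hydrophobin rather than raising.
    """
    if not motifs:
        return Classification(seq_id=record.id, label=NOT_HYDROPHOBIN, confidence=0.0)
    cents = centroids if centroids is not None else load_default_centroids()
    vec = np.asarray(motifs[0].spacing, dtype=float)
    dists = {label: float(np.linalg.norm(vec - c)) for label, c in cents.items()}
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    (best, d1), (_, d2) = ranked[0], ranked[1]
    if abs(d1 - d2) < 1e-12:
        loop = motifs[0].loops.get("C7-C8")
        if loop is not None and loop.sequence:
            best = "class_I" if physchem.gravy(loop.sequence) > 0 else "class_II"
    return Classification(seq_id=record.id, label=best, confidence=abs(d2 - d1))


# ---------------------------------------------------------------------------
# non-canonical feature mining
# ---------------------------------------------------------------------------


def mine_noncanonical(
    record: SequenceRecord, motifs: Sequence[CysMotif]
) -> MiningReport:
    """Flag non-canonical hydrophobin features on one sequence.

    - five-disulfide candidate: exactly 10 cysteines in a sequence shorter
      than 250 residues (a compact single domain with a putative fifth bond);
    - extended N-tail: at least 70 residues precede the first cysteine;
    - polyhydrophobin: more than one motif in a chain longer than 250
      residues, labelled di/tri/.../penta by domain count.
    """
    seq = record.residues
    cys_count = seq.count("C")
    first_c = seq.find("C")
    tail = first_c if first_c >= 0 else len(seq)

    domain_count = len(motifs)
    poly = len(seq) > POLY_MIN_LENGTH and domain_count >= 2
    return MiningReport(
        seq_id=record.id,
        motif_found=domain_count > 0,
        five_disulfide_candidate=(cys_count == TEN_CYS_COUNT and len(seq) < TEN_CYS_MAX_LENGTH),
        extended_ntail=tail >= EXTENDED_TAIL_MIN,
        n_tail_length=tail,
        polyhydrophobin=poly,
        domain_count=domain_count,
        domain_label=_POLY_LABELS.get(domain_count, f"{domain_count}-domain"),
    )


def mining_table(reports: Iterable[MiningReport]) -> pd.DataFrame:
    """One row per sequence with all mining flags."""
    return pd.DataFrame([vars(r) for r in reports])


def motif_json(record: SequenceRecord, motifs: Sequence[CysMotif]) -> dict:
    """JSON-serialisable motif dump with 1-based inclusive loop coordinates."""
    return {
        "seq_id": record.id,
        "motifs": [
            {
                "cys_positions": list(m.cys_positions),
                "spacing": list(m.spacing),
                "doublet_ordinals": sorted(map(list, m.doublet_ordinals)),
                "loops": {
                    name: {"start": lp.start, "end": lp.end, "sequence": lp.sequence}
                    for name, lp in m.loops.items()
                },
            }
            for m in motifs
        ],
    }
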