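"""Model-quality assessment: Calpha RMSD, TM-score, lDDT-Calpha.

Predicted models are scored against experimental structures with three
complementary metrics:

- **Calpha RMSD** after optimal rigid (Kabsch) superposition — a global
  measure; < 2.5 A marks a good prediction.
- **TM-score** — mean of 1/(1 + (d_i/d0)^2) over aligned Calpha pairs,
  normalised by the reference (experimental) chain length through
  d0(L) = 1.24 (L - 15)^(1/3) - 1.8 (floored at 0.5 A for the short chains
  typical of hydrophobins); maximised over superpositions by iterative
  fragment seeding; > 0.6 indicates the same fold.
- **lDDT-Calpha** — superposition-free: the fraction of Calpha-Calpha
  distances under 15 A in the reference that are preserved within
  tolerances {0.5, 1, 2, 4} A, averaged over the four tolerances; > 0.6
  indicates a locally accurate model.

Against an NMR ensemble, metrics are computed per member and the member
with the lowest Calpha RMSD is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .structio import StructureModel

#: quality cut-offs marking a good prediction
RMSD_CUTOFF = 2.5
LDDT_CUTOFF = 0.6
TM_CUTOFF = 0.6

#: lDDT parameters
LDDT_INCLUSION_RADIUS = 15.0
LDDT_TOLERANCES = (0.5, 1.0, 2.0, 4.0)


class DegenerateInputError(ValueError):
    """Too few or collinear points for a rigid superposition."""


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map x -> R (x - mobile_centroid) + reference_centroid."""

    rotation: np.ndarray  # (3,3) proper rotation
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T + self.reference_centroid

    @property
    def translation(self) -> np.ndarray:
        return self.reference_centroid - self.rotation @ self.mobile_centroid


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of paired point sets.

    A proper rotation is enforced via the determinant correction of the
    SVD solution. Raises :class:`DegenerateInputError` for fewer than 3
    points or collinear reference points (the rotation about the line is
    then unconstrained).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise DegenerateInputError("at least 3 paired points required")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    p, q = mobile - cm, reference - cr
    s = np.linalg.svd(q, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateInputError("reference points are (near-)collinear")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = p @ rot.T - q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=rot, mobile_centroid=cm, reference_centroid=cr, rmsd=rmsd)


def pair_residues(
    model: StructureModel, reference: StructureModel
) -> list[tuple[int, int]]:
    """Residue correspondence as (model index, reference index) pairs.

    Identical sequences pair by index; otherwise a global alignment
    (match +1, mismatch -1, gap -2) supplies the aligned, non-gap pairs.
    Pairs lacking a Calpha in either partner are dropped.
    """
    sm, sr = model.sequence(), reference.sequence()
    if sm == sr:
        pairs = [(i, i) for i in range(len(sm))]
    else:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        aln = aligner.align(sm, sr)[0]
        pairs = []
        for (ms, me), (rs, re) in zip(*aln.aligned):
            pairs.extend((ms + k, rs + k) for k in range(me - ms))
    return [
        (i, j)
        for i, j in pairs
        if model.residues[i].ca is not None and reference.residues[j].ca is not None
    ]


def tm_d0(l_ref: int) -> float:
    """Length-dependent TM-score normalisation distance, floored at 0.5 A."""
    if l_ref <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)


@dataclass(frozen=True)
class TMResult:
    score: float
    d0: float
    n_aligned: int


def tm_from_distances(d: np.ndarray, d0: float, l_ref: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def tm_score(
    model: StructureModel,
    reference: StructureModel,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> TMResult:
    """TM-score of ``model`` against ``reference`` (reference-normalised).

    The score is maximised over rigid superpositions by iterative seeding:
    the full aligned chain and contiguous fragments of length L/2 and L/4
    at sliding offsets each seed a superposition, which is refined by
    re-superposing on the residues closer than max(d0, 4.5 A) until the
    inlier set is stable; the best final score over all seeds is reported.
    """
    if pairing is None:
        pairing = pair_residues(model, reference)
    if len(pairing) < 3:
        raise DegenerateInputError("fewer than 3 corresponding residue pairs")
    mob = np.array([model.residues[i].ca for i, _ in pairing])
    ref = np.array([reference.residues[j].ca for _, j in pairing])
    l_ref = sum(1 for r in reference.residues if r.ca is not None)
    d0 = tm_d0(l_ref)
    inlier_cut = max(d0, 4.5)
    n = len(pairing)

    seeds: list[np.ndarray] = [np.arange(n)]
    for frac in (2, 4):
        flen = max(3, n // frac)
        step = max(1, flen // 2)
        for start in range(0, n - flen + 1, step):
            seeds.append(np.arange(start, start + flen))

    best = 0.0
    for seed in seeds:
        idx = seed
        prev: np.ndarray | None = None
        for _ in range(30):
            try:
                sup = kabsch_superpose(mob[idx], ref[idx])
            except DegenerateInputError:
                break
            d = np.linalg.norm(sup.apply(mob) - ref, axis=1)
            inliers = np.flatnonzero(d < inlier_cut)
            score = tm_from_distances(d, d0, l_ref)
            best = max(best, score)
            if len(inliers) < 3 or (prev is not None and np.array_equal(inliers, prev)):
                break
            prev = idx = inliers
    return TMResult(score=best, d0=d0, n_aligned=n)


def lddt_ca(
    model: StructureModel,
    reference: StructureModel,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Superposition-free lDDT over Calpha-Calpha distances.

    Considers reference pairs (i != j) closer than 15 A; a pair is
    preserved at tolerance t when |d_model - d_ref| < t; the score averages
    the preserved fraction over t in {0.5, 1, 2, 4} A.
    """
    if pairing is None:
        pairing = pair_residues(model, reference)
    if len(pairing) < 2:
        raise DegenerateInputError("fewer than 2 corresponding residue pairs")
    mob = np.array([model.residues[i].ca for i, _ in pairing])
    ref = np.array([reference.residues[j].ca for _, j in pairing])
    dref = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    dmod = np.linalg.norm(mob[:, None, :] - mob[None, :, :], axis=-1)
    iu = np.triu_indices(len(ref), k=1)
    mask = dref[iu] < LDDT_INCLUSION_RADIUS
    if not mask.any():
        raise DegenerateInputError("no Calpha pairs within the inclusion radius")
    delta = np.abs(dmod[iu][mask] - dref[iu][mask])
    fractions = [(delta < t).mean() for t in LDDT_TOLERANCES]
    return float(np.mean(fractions))


@dataclass(frozen=True)
class ComparisonResult:
    """Metrics of one predicted model against one experimental structure."""

    rmsd: float
    tm_score: float
    lddt_ca: float
    n_aligned: int
    d0: float
    chosen_model_index: int
    rmsd_good: bool
    lddt_good: bool
    tm_good: bool

    @property
    def all_good(self) -> bool:
        return self.rmsd_good and self.lddt_good and self.tm_good


def benchmark_model(
    predicted: StructureModel, experimental: Sequence[StructureModel]
) -> ComparisonResult:
    """Score a predicted model against an experimental structure or ensemble.

    All metrics are computed against every ensemble member; the member with
    the lowest Calpha RMSD is chosen and its metrics reported with its
    model index. Quality flags apply the standard cut-offs (RMSD < 2.5 A,
    lDDT-Calpha > 0.6, TM-score > 0.6).
    """
    if not experimental:
        raise ValueError("experimental ensemble is empty")
    best: ComparisonResult | None = None
    for member in experimental:
        pairing = pair_residues(predicted, member)
        if len(pairing) < 3:
            raise DegenerateInputError(
                f"fewer than 3 aligned residues against model {member.model_index}"
            )
        mob = np.array([predicted.residues[i].ca for i, _ in pairing])
        ref = np.array([member.residues[j].ca for _, j in pairing])
        rmsd = kabsch_superpose(mob, ref).rmsd
        tm = tm_score(predicted, member, pairing)
        lddt = lddt_ca(predicted, member, pairing)
        result = ComparisonResult(
            rmsd=rmsd,
            tm_score=tm.score,
            lddt_ca=lddt,
            n_aligned=len(pairing),
            d0=tm.d0,
            chosen_model_index=member.model_index,
            rmsd_good=rmsd < RMSD_CUTOFF,
            lddt_good=lddt > LDDT_CUTOFF,
            tm_good=tm.score > TM_CUTOFF,
        )
        if best is None or result.rmsd < best.rmsd:
            best = result
    return best


def benchmark_table(
    entries: Sequence[tuple[str, StructureModel, Sequence[StructureModel], str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch benchmark: entries are (pair id, predicted, ensemble, class label).

    Returns the per-pair table and a per-class mean +/- sd summary of the
    three metrics.
    """
    rows = []
    for pair_id, predicted, ensemble, label in entries:
        r = benchmark_model(predicted, ensemble)
        rows.append(
            {
                "pair_id": pair_id,
                "class_label": label,
                "rmsd": r.rmsd,
                "tm_score": r.tm_score,
                "lddt_ca": r.lddt_ca,
                "n_aligned": r.n_aligned,
                "d0": r.d0,
                "chosen_model_index": r.chosen_model_index,
                "rmsd_good": r.rmsd_good,
                "lddt_good": r.lddt_good,
                "tm_good": r.tm_good,
            }
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("class_label")[["rmsd", "tm_score", "lddt_ca"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return table, summary
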