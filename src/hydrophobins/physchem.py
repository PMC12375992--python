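"""Physicochemical sequence profiles: GRAVY, isoelectric point, composition.

GRAVY (grand average of hydropathy) is the arithmetic mean of per-residue
Kyte-Doolittle hydropathy values; hydrophobins typically fall between 0 and
1, well above the -0.5 to -0.3 range of whole proteomes. The isoelectric
point is predicted with the Bjellqvist pK set under the Henderson-
Hasselbalch model, solving net charge = 0 by bisection. All cysteines are
treated as free (titratable) thiols: this is a sequence-only prediction
that ignores disulfide state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .seqio import SequenceRecord

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: residues excluded from the GRAVY mean (ambiguity codes, selenocysteine)
AMBIGUOUS = set("XBZU")

# Bjellqvist pK values. Basic groups carry positive charge below their pK,
# acidic groups negative charge above. The N-terminal alpha-amino pK depends
# on the first residue; the C-terminal carboxyl pK on the last.
_PK_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PK_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PK_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
_PK_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}


class UndefinedScoreError(ValueError):
    """No residues usable for the requested score."""


@dataclass(frozen=True)
class PhyschemProfile:
    """Physicochemical summary of one sequence."""

    seq_id: str
    length: int
    cys_count: int
    gravy: float
    pi: float
    composition: Mapping[str, float]


def gravy(residues: str) -> float:
    """Mean Kyte-Doolittle hydropathy over non-ambiguous residues.

    Ambiguous codes (X/B/Z) and selenocysteine are excluded from the mean
    rather than imputed.
    """
    values = [KYTE_DOOLITTLE[c] for c in residues if c not in AMBIGUOUS]
    if not values:
        raise UndefinedScoreError("no non-ambiguous residues; GRAVY undefined")
    return sum(values) / len(values)


def net_charge(residues: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (Bjellqvist pK set)."""
    charge = 0.0
    pk_nt = _PK_NTERM_BY_RESIDUE.get(residues[0], _PK_POSITIVE["Nterm"]) if residues else 7.5
    pk_ct = _PK_CTERM_BY_RESIDUE.get(residues[-1], _PK_NEGATIVE["Cterm"]) if residues else 3.55
    charge += 1.0 / (1.0 + 10.0 ** (ph - pk_nt))
    charge -= 1.0 / (1.0 + 10.0 ** (pk_ct - ph))
    for aa in residues:
        if aa in ("K", "R", "H"):
            charge += 1.0 / (1.0 + 10.0 ** (ph - _PK_POSITIVE[aa]))
        elif aa in ("D", "E", "C", "Y"):
            charge -= 1.0 / (1.0 + 10.0 ** (_PK_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(residues: str, tol: float = 1e-3) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Convergence criterion: |net charge| < ``tol`` (default 1e-3 charge
    units). The charge function is strictly decreasing in pH, positive at
    pH 0 (protonated amine) and negative at pH 14 (deprotonated carboxyl),
    so a root always exists.
    """
    if not residues:
        raise UndefinedScoreError("empty sequence; pI undefined")
    lo, hi = 0.0, 14.0
    # bisect to a pH interval far tighter than the charge tolerance so the
    # result also pins the zero *crossing* (the charge curve can be nearly
    # flat around pI for sequences with few ionizable side chains)
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = 0.5 * (lo + hi)
    assert abs(net_charge(residues, pi)) < tol
    return pi


def residue_composition(residues: str) -> dict[str, float]:
    """Percent of each amino-acid code present; absent codes omitted."""
    if not residues:
        raise UndefinedScoreError("empty sequence; composition undefined")
    n = len(residues)
    comp: dict[str, float] = {}
    for aa in sorted(set(residues)):
        comp[aa] = 100.0 * residues.count(aa) / n
    return comp


def profile(record: SequenceRecord) -> PhyschemProfile:
    """Full physicochemical profile of one record."""
    return PhyschemProfile(
        seq_id=record.id,
        length=len(record),
        cys_count=record.residues.count("C"),
        gravy=gravy(record.residues),
        pi=isoelectric_point(record.residues),
        composition=residue_composition(record.residues),
    )


def profile_table(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Profiles for many records: one row each, one column per residue percent."""
    rows = []
    for rec in records:
        p = profile(rec)
        row: dict[str, object] = {
            "seq_id": p.seq_id,
            "length": p.length,
            "cys_count": p.cys_count,
            "pi": round(p.pi, 4),
            "gravy": round(p.gravy, 4),
        }
        for aa, pct in p.composition.items():
            row[f"pct_{aa}"] = round(pct, 4)
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
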