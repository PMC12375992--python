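"""Structure parsing, disulfide topology, and solvent-accessible surface area.

PDB files (single- or multi-model) are parsed with gemmi into light
:class:`StructureModel` objects holding ordered residues with Calpha and
cysteine Sgamma coordinates plus the temperature-factor column, which for
predicted models carries per-residue pLDDT confidence. Disulfide bonds are
detected from Sgamma-Sgamma distances and reported as cysteine *ordinal*
pairs (C1, C2, ... in sequence order), so topologies can be compared across
proteins with different residue numbering. The canonical hydrophobin
topology is {C1-C6, C2-C5, C3-C4, C7-C8}.

SASA uses Shrake-Rupley sphere-point quadrature with Bondi van der Waals
radii and a 1.4 A water probe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

#: canonical four-disulfide topology of the cysteine octet
CANONICAL_TOPOLOGY = frozenset({(1, 6), (2, 5), (3, 4), (7, 8)})

#: default Sgamma-Sgamma distance cutoff; a covalent S-S bond is ~2.05 A,
#: 2.5 A excludes non-bonded contacts
SS_CUTOFF = 2.5

#: Bondi van der Waals radii (A) by element symbol
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "SE": 1.90, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


class StructureParseError(ValueError):
    """Malformed or empty coordinate input; message names the line if known."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) in A


@dataclass
class ResidueRecord:
    """One residue: author numbering, one-letter code, key coordinates."""

    number: int
    icode: str
    aa: str  # one-letter code, 'X' if unknown
    ca: np.ndarray | None
    sg: np.ndarray | None
    confidence: float  # temperature-factor column (pLDDT for predictions)
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class StructureModel:
    """One coordinate model (one member of an NMR/predicted ensemble)."""

    model_index: int  # 1-based, per MODEL record
    chain_id: str
    residues: list[ResidueRecord]
    het_atoms: list[Atom] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array over residues that have a Calpha."""
        return np.array([r.ca for r in self.residues if r.ca is not None])

    def cys_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.aa == "C"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with every coordinate mapped through x -> R x + t."""

        def tx(v: np.ndarray | None) -> np.ndarray | None:
            return None if v is None else rotation @ v + translation

        residues = [
            ResidueRecord(
                number=r.number, icode=r.icode, aa=r.aa,
                ca=tx(r.ca), sg=tx(r.sg), confidence=r.confidence,
                atoms=[Atom(a.name, a.element, tx(a.xyz)) for a in r.atoms],
            )
            for r in self.residues
        ]
        het = [Atom(a.name, a.element, tx(a.xyz)) for a in self.het_atoms]
        return StructureModel(self.model_index, self.chain_id, residues, het)


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise StructureParseError(
                    f"line {lineno}: ATOM/HETATM record shorter than coordinate fields"
                )
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(
                    f"line {lineno}: malformed coordinate field"
                ) from exc


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Blank altloc wins; else highest occupancy; ties resolved toward 'A'."""
    blanks = [a for a in atoms if not a.altloc]
    if blanks:
        return blanks[0]
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def parse_structure(source: str | Path, chain: str | None = None) -> list[StructureModel]:
    """Parse PDB text (or a path to it) into a list of models.

    One :class:`StructureModel` per MODEL block (a single block for X-ray
    files). Alternate locations are resolved by occupancy; HETATM records
    (waters excluded) are kept only for SASA occlusion. ``chain`` selects a
    chain id; by default the first chain containing amino acids is used.

    Raises :class:`StructureParseError` on empty input or malformed
    fixed-column coordinate fields.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    _validate_pdb_lines(text)
    if not any(line.startswith("ATOM") for line in text.splitlines()):
        raise StructureParseError("no ATOM records in input")

    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    models: list[StructureModel] = []
    for mi, gm in enumerate(st, start=1):
        gchain = None
        for ch in gm:
            if chain is not None and ch.name != chain:
                continue
            if any(gemmi.find_tabulated_residue(res.name) is not None
                   and gemmi.find_tabulated_residue(res.name).is_amino_acid()
                   for res in ch):
                gchain = ch
                break
        if gchain is None:
            continue
        residues: list[ResidueRecord] = []
        het: list[Atom] = []
        for res in gchain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            chosen = [_pick_altloc(group) for group in by_name.values()]
            if not is_aa:
                if res.name != "HOH":
                    het.extend(
                        Atom(a.name, a.element.name.upper(),
                             np.array([a.pos.x, a.pos.y, a.pos.z]))
                        for a in chosen
                    )
                continue
            atoms = [
                Atom(a.name, a.element.name.upper(), np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in chosen
            ]
            ca = next((a.xyz for a in atoms if a.name == "CA"), None)
            sg = next((a.xyz for a in atoms if a.name == "SG"), None)
            bvals = [a.b_iso for a in chosen]
            one = info.one_letter_code.upper() if info.one_letter_code.isalpha() else "X"
            residues.append(
                ResidueRecord(
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    aa=one,
                    ca=ca,
                    sg=sg,
                    confidence=float(np.mean(bvals)) if bvals else 0.0,
                    atoms=atoms,
                )
            )
        residues.sort(key=lambda r: (r.number, r.icode))
        models.append(StructureModel(mi, gchain.name, residues, het))
    if not models:
        raise StructureParseError("no protein chain found in input")
    return models


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_pdb(models: list[StructureModel], path: str | Path) -> None:
    """Write models as multi-model PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = "hydrophobins"
    for model in models:
        gm = gemmi.Model(model.model_index)
        ch = gemmi.Chain(model.chain_id or "A")
        for res in model.residues:
            gr = gemmi.Residue()
            gr.name = _THREE.get(res.aa, "UNK")
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            atoms = res.atoms or []
            if not atoms and res.ca is not None:
                atoms = [Atom("CA", "C", res.ca)]
            for a in atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*map(float, a.xyz))
                ga.b_iso = res.confidence
                ga.occ = 1.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
        st.add_model(gm)
    Path(path).write_text(st.make_pdb_string())


def build_model(
    ca_coords: np.ndarray,
    sequence: str | None = None,
    sg_coords: dict[int, np.ndarray] | None = None,
    model_index: int = 1,
    chain_id: str = "A",
    confidence: float = 0.0,
) -> StructureModel:
    """Construct a Calpha-trace model from coordinates (synthetic inputs).

    ``sg_coords`` maps 0-based residue indices to Sgamma positions for
    cysteines.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    n = len(ca_coords)
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError("sequence length must match coordinate count")
    sg_coords = sg_coords or {}
    residues = []
    for i in range(n):
        atoms = [Atom("CA", "C", ca_coords[i])]
        sg = sg_coords.get(i)
        if sg is not None:
            sg = np.asarray(sg, dtype=float)
            atoms.append(Atom("SG", "S", sg))
        residues.append(
            ResidueRecord(
                number=i + 1, icode="", aa=seq[i], ca=ca_coords[i], sg=sg,
                confidence=confidence, atoms=atoms,
            )
        )
    return StructureModel(model_index, chain_id, residues)


# ---------------------------------------------------------------------------
# disulfide topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DisulfideTopology:
    """Disulfide bonds as cysteine ordinal pairs, vs the canonical pattern."""

    bonds: frozenset[tuple[int, int]]
    free_cysteines: tuple[int, ...]
    canonical_match: bool
    mapping_to_canonical: dict[tuple[int, int], tuple[int, int] | None] | None = None

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def detect_disulfides(
    model: StructureModel,
    cutoff: float = SS_CUTOFF,
    canonical_reference: StructureModel | None = None,
) -> DisulfideTopology:
    """Pair cysteine Sgamma atoms into disulfide bonds.

    Greedy minimum-distance matching under ``cutoff``: candidate pairs are
    sorted by (distance, lower ordinal) and accepted while both partners are
    unassigned, which makes the result independent of input atom order.
    Unpaired cysteines are reported as free, not an error. When a
    ``canonical_reference`` with the canonical topology is supplied, a
    spatial bond correspondence is computed by superposing the model onto
    the reference and matching bond midpoints, so a shifted connectivity
    (e.g. the canonical C1-C6 appearing as C4-C7 in a 10-Cys protein) can
    be read off.
    """
    cys = model.cys_residues()
    with_sg = [(i + 1, r.sg) for i, r in enumerate(cys) if r.sg is not None]
    pairs = []
    for a in range(len(with_sg)):
        for b in range(a + 1, len(with_sg)):
            oi, si = with_sg[a]
            oj, sj = with_sg[b]
            d = float(np.linalg.norm(si - sj))
            if d < cutoff:
                pairs.append((d, oi, oj))
    pairs.sort()
    used: set[int] = set()
    bonds: set[tuple[int, int]] = set()
    for d, i, j in pairs:
        if i not in used and j not in used:
            bonds.add((i, j))
            used.update((i, j))
    free = tuple(o for o, _ in with_sg if o not in used)
    canonical = frozenset(bonds) == CANONICAL_TOPOLOGY

    mapping = None
    if canonical:
        mapping = {b: b for b in sorted(bonds)}
    elif canonical_reference is not None and bonds:
        mapping = _map_bonds_to_reference(model, bonds, canonical_reference)
    return DisulfideTopology(
        bonds=frozenset(bonds),
        free_cysteines=free,
        canonical_match=canonical,
        mapping_to_canonical=mapping,
    )


def _bond_midpoints(model: StructureModel, bonds: set[tuple[int, int]] | frozenset) -> dict:
    cys = model.cys_residues()
    return {
        (i, j): 0.5 * (cys[i - 1].sg + cys[j - 1].sg)
        for (i, j) in bonds
        if cys[i - 1].sg is not None and cys[j - 1].sg is not None
    }


def _map_bonds_to_reference(
    model: StructureModel, bonds: set[tuple[int, int]], reference: StructureModel
) -> dict[tuple[int, int], tuple[int, int] | None]:
    """Greedy nearest-midpoint correspondence after Calpha superposition."""
    from .structcompare import kabsch_superpose, pair_residues

    ref_topo = detect_disulfides(reference)
    ref_mid = _bond_midpoints(reference, ref_topo.bonds)
    pairing = pair_residues(model, reference)
    mob = np.array([model.residues[i].ca for i, _ in pairing])
    ref = np.array([reference.residues[j].ca for _, j in pairing])
    sup = kabsch_superpose(mob, ref)
    mod_mid = {
        b: sup.rotation @ (m - sup.mobile_centroid) + sup.reference_centroid
        for b, m in _bond_midpoints(model, bonds).items()
    }
    candidates = sorted(
        (float(np.linalg.norm(mm - rm)), mb, rb)
        for mb, mm in mod_mid.items()
        for rb, rm in ref_mid.items()
    )
    mapping: dict[tuple[int, int], tuple[int, int] | None] = {b: None for b in bonds}
    taken: set[tuple[int, int]] = set()
    for _, mb, rb in candidates:
        if mapping[mb] is None and rb not in taken:
            mapping[mb] = rb
            taken.add(rb)
    return mapping


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass(frozen=True)
class SasaResult:
    per_residue: np.ndarray  # A^2, aligned with model.residues
    total: float  # A^2, includes non-water HETATM contribution


def shrake_rupley_sasa(
    model: StructureModel, probe: float = 1.4, n_points: int = 960
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each heavy atom is expanded by the probe radius and sampled with
    ``n_points`` quasi-uniform sphere points; points falling inside any
    neighbouring expanded sphere are occluded. Missing atoms simply do not
    contribute (a completeness warning is emitted for models that look
    Calpha-only), so absolute values on incomplete models are lower bounds.
    """
    coords, radii, owner = [], [], []
    for ri, res in enumerate(model.residues):
        for a in res.atoms:
            coords.append(a.xyz)
            radii.append(BONDI_RADII.get(a.element.upper(), DEFAULT_RADIUS))
            owner.append(ri)
    for a in model.het_atoms:
        coords.append(a.xyz)
        radii.append(BONDI_RADII.get(a.element.upper(), DEFAULT_RADIUS))
        owner.append(-1)
    if not coords:
        raise ValueError("model has no atoms")
    if model.residues and all(len(r.atoms) <= 2 for r in model.residues):
        warnings.warn(
            "model appears to lack full heavy-atom detail; SASA computed over available atoms"
        )
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    # exactly coincident duplicates (altloc artefacts) count once
    _, keep = np.unique(np.round(coords, 6), axis=0, return_index=True)
    keep = np.sort(keep)
    coords, radii = coords[keep], radii[keep]
    owner = [owner[k] for k in keep]
    expanded = radii + probe
    unit = _sphere_points(n_points)

    tree = cKDTree(coords)
    per_residue = np.zeros(len(model.residues))
    total = 0.0
    rmax = float(expanded.max())
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= expanded[j] ** 2
            if not accessible.any():
                break
        area = 4.0 * math.pi * expanded[i] ** 2 * accessible.sum() / n_points
        total += area
        if owner[i] >= 0:
            per_residue[owner[i]] += area
    return SasaResult(per_residue=per_residue, total=total)
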