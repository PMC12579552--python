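"""Simplified native geometry validation.

Provides the geometry inputs of the composite score that can be computed
without curated torsion libraries: a MolProbity-style clashscore (van der
Waals overlap >= 0.4 A per 1000 atoms), RMS deviations of bonds and angles
from a packaged ideal-value table, and the RMSD between the A and B
conformers of a two-state model.  MolProbity score, Ramachandran, rotamer
and C-beta outliers are deliberately not computed natively; they can be
supplied through the pipeline's ingestion path.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    AtomRecord,
    ResidueKey,
    ResidueSelection,
    StructureModel,
    ValidationError,
)

__all__ = [
    "IdealGeometryTable",
    "GeometryMetrics",
    "Clash",
    "clashscore",
    "bond_angle_rms",
    "conformer_rmsd",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: single-bond covalent radii (A) for distance-based bond inference
COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "SE": 1.20,
    "P": 1.07,
}
BOND_TOLERANCE = 0.45  # A beyond covalent radius sum


@dataclass
class IdealGeometryTable:
    """Ideal bond lengths, angles and vdW radii.

    Keys use "*" as a wildcard residue name applying to all standard amino
    acids.  Bonds/angles are (resname, "N1-N2"[-N3]) -> value; link entries
    span the peptide bond between sequence-adjacent residues.
    """

    bonds: Dict[Tuple[str, str], float] = field(default_factory=dict)
    angles: Dict[Tuple[str, str], float] = field(default_factory=dict)
    link_bonds: Dict[str, float] = field(default_factory=dict)
    link_angles: Dict[str, float] = field(default_factory=dict)
    vdw: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def load_default(cls) -> "IdealGeometryTable":
        text = (
            resources.files("trxscore.data")
            .joinpath("ideal_geometry.tsv")
            .read_text()
        )
        return cls.from_tsv(text)

    @classmethod
    def from_tsv(cls, text: str) -> "IdealGeometryTable":
        table = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            if kind == "vdw":
                element, value = parts[1], float(parts[2])
                if not (1.0 < value < 2.5):
                    raise ValidationError(f"vdW radius {value} outside (1.0, 2.5)")
                table.vdw[element.upper()] = value
                continue
            resname, atoms, value = parts[1], parts[2], float(parts[3])
            if kind in ("bond", "link_bond"):
                if not (0.5 < value < 3.0):
                    raise ValidationError(f"bond length {value} outside (0.5, 3.0)")
            elif kind in ("angle", "link_angle"):
                if not (0.0 < value < 180.0):
                    raise ValidationError(f"angle {value} outside (0, 180)")
            if kind == "bond":
                table.bonds[(resname, atoms)] = value
            elif kind == "angle":
                table.angles[(resname, atoms)] = value
            elif kind == "link_bond":
                table.link_bonds[atoms] = value
            elif kind == "link_angle":
                table.link_angles[atoms] = value
            else:
                raise ValidationError(f"unknown geometry table record {kind!r}")
        return table

    def residue_bonds(self, resname: str) -> Dict[str, float]:
        out = {a: v for (r, a), v in self.bonds.items() if r == "*"}
        out.update({a: v for (r, a), v in self.bonds.items() if r == resname})
        return out

    def residue_angles(self, resname: str) -> Dict[str, float]:
        out = {a: v for (r, a), v in self.angles.items() if r == "*"}
        out.update({a: v for (r, a), v in self.angles.items() if r == resname})
        return out

    def vdw_radius(self, element: str) -> Optional[float]:
        return self.vdw.get(element.upper())


@dataclass
class Clash:
    atom1: Tuple[ResidueKey, str, str]  # (residue, atom_name, altloc)
    atom2: Tuple[ResidueKey, str, str]
    distance: float
    overlap: float


@dataclass
class GeometryMetrics:
    clashscore: float
    rms_bond: Optional[float]
    rms_angle: Optional[float]
    rmsd_AB: Optional[float]
    n_bonds: int = 0
    n_angles: int = 0
    n_contacts: int = 0
    clashes: List[Clash] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Bonded topology
# ---------------------------------------------------------------------------

def _altloc_compatible(a: str, b: str) -> bool:
    """Atoms can interact/bond only within one conformer: same label or blank."""
    return a == b or a == "" or b == ""


def _flatten(model: StructureModel, include_hydrogens: bool):
    flat = []
    for key, atoms in model.residues.items():
        for atom in atoms:
            if atom.is_hydrogen and not include_hydrogens:
                continue
            flat.append((key, atom))
    return flat


def _sequence_adjacent(k1: ResidueKey, k2: ResidueKey) -> bool:
    return (
        k1.chain_id == k2.chain_id
        and abs(k1.residue_number - k2.residue_number) == 1
        and k1.insertion_code == "" and k2.insertion_code == ""
    )


def _bond_graph(flat: Sequence[Tuple[ResidueKey, AtomRecord]]) -> Dict[int, List[int]]:
    """Distance-inferred covalent bonds within residues plus peptide C-N links."""
    adjacency: Dict[int, List[int]] = {i: [] for i in range(len(flat))}

    def try_bond(i: int, j: int, max_dist: float) -> None:
        ai, aj = flat[i][1], flat[j][1]
        if not _altloc_compatible(ai.altloc, aj.altloc):
            return
        d = float(np.linalg.norm(ai.position - aj.position))
        if d <= max_dist:
            adjacency[i].append(j)
            adjacency[j].append(i)

    by_res: Dict[ResidueKey, List[int]] = {}
    for i, (key, _) in enumerate(flat):
        by_res.setdefault(key, []).append(i)

    for key, idxs in by_res.items():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1:]:
                ri = COVALENT_RADIUS.get(flat[i][1].element.upper(), 0.77)
                rj = COVALENT_RADIUS.get(flat[j][1].element.upper(), 0.77)
                try_bond(i, j, ri + rj + BOND_TOLERANCE)
    keys = list(by_res)
    for a, ka in enumerate(keys):
        for kb in keys[a + 1:]:
            if not _sequence_adjacent(ka, kb):
                continue
            first, second = (ka, kb) if ka.residue_number < kb.residue_number else (kb, ka)
            for i in by_res[first]:
                if flat[i][1].atom_name != "C":
                    continue
                for j in by_res[second]:
                    if flat[j][1].atom_name != "N":
                        continue
                    try_bond(i, j, 1.329 + 0.6)
    return adjacency


def _within_three_bonds(adjacency: Dict[int, List[int]], i: int, j: int) -> bool:
    if i == j:
        return True
    seen = {i}
    frontier = deque([(i, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if depth == 3:
            continue
        for nb in adjacency[node]:
            if nb == j:
                return True
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, depth + 1))
    return False


# ---------------------------------------------------------------------------
# Clashscore
# ---------------------------------------------------------------------------

def clashscore(
    model: StructureModel,
    table: Optional[IdealGeometryTable] = None,
    overlap_cutoff: float = 0.4,
    include_hydrogens: bool = False,
) -> Tuple[float, List[Clash]]:
    """MolProbity-style steric clash rate: clashes per 1000 atoms.

    A clash is an unbonded pair (more than 3 bonds apart on the covalent
    graph) whose vdW overlap r1 + r2 - d is at least ``overlap_cutoff``.
    Pairs in different non-blank conformers never clash.  Atoms are counted
    once per altloc copy.
    """
    if table is None:
        table = IdealGeometryTable.load_default()
    flat = _flatten(model, include_hydrogens)
    if len(flat) < 2:
        return 0.0, []
    adjacency = _bond_graph(flat)
    coords = np.array([a.position for _, a in flat])
    radii = np.array([
        table.vdw_radius(a.element) or 1.7 for _, a in flat
    ])
    max_pair = 2 * radii.max() - overlap_cutoff
    tree = cKDTree(coords)
    clashes: List[Clash] = []
    for i, j in sorted(tree.query_pairs(r=max_pair)):
        ki, ai = flat[i]
        kj, aj = flat[j]
        if not _altloc_compatible(ai.altloc, aj.altloc):
            continue
        d = float(np.linalg.norm(ai.position - aj.position))
        overlap = radii[i] + radii[j] - d
        if overlap < overlap_cutoff:
            continue
        if _within_three_bonds(adjacency, i, j):
            continue
        clashes.append(Clash(
            atom1=(ki, ai.atom_name, ai.altloc),
            atom2=(kj, aj.atom_name, aj.altloc),
            distance=d,
            overlap=float(overlap),
        ))
    score = 1000.0 * len(clashes) / len(flat)
    return score, clashes


# ---------------------------------------------------------------------------
# Bond / angle RMS
# ---------------------------------------------------------------------------

def _angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _conformer_atom_maps(
    atoms: Sequence[AtomRecord],
) -> Dict[str, Dict[str, AtomRecord]]:
    """Atom lookups per conformer label; blank atoms back every conformer."""
    labels = sorted({a.altloc for a in atoms if a.altloc}) or [""]
    out: Dict[str, Dict[str, AtomRecord]] = {}
    for label in labels:
        lookup: Dict[str, AtomRecord] = {}
        for atom in atoms:
            if atom.altloc == "":
                lookup.setdefault(atom.atom_name, atom)
        for atom in atoms:
            if atom.altloc == label:
                lookup[atom.atom_name] = atom
        out[label] = lookup
    return out


def bond_angle_rms(
    model: StructureModel,
    table: Optional[IdealGeometryTable] = None,
) -> Tuple[Optional[float], Optional[float], int, int]:
    """RMS deviation of observed bonds/angles from the ideal table.

    Evaluated per conformer (alternative conformers are separate instances);
    residues not in the standard set and atoms without a template entry are
    skipped.  Returns (rms_bond, rms_angle, n_bonds, n_angles); the RMS values
    are None when nothing matched.
    """
    if table is None:
        table = IdealGeometryTable.load_default()
    bond_dev: List[float] = []
    angle_dev: List[float] = []

    per_res = {
        key: _conformer_atom_maps(atoms)
        for key, atoms in model.residues.items()
        if key.residue_name in STANDARD_AA
    }
    for key, conformers in per_res.items():
        bonds = table.residue_bonds(key.residue_name)
        angles = table.residue_angles(key.residue_name)
        for lookup in conformers.values():
            for names, ideal in bonds.items():
                n1, n2 = names.split("-")
                if n1 in lookup and n2 in lookup:
                    d = np.linalg.norm(lookup[n1].position - lookup[n2].position)
                    bond_dev.append(float(d) - ideal)
            for names, ideal in angles.items():
                n1, n2, n3 = names.split("-")
                if n1 in lookup and n2 in lookup and n3 in lookup:
                    ang = _angle_deg(
                        lookup[n1].position, lookup[n2].position, lookup[n3].position
                    )
                    angle_dev.append(ang - ideal)

    keys = list(per_res)
    for a, ka in enumerate(keys):
        for kb in keys[a + 1:]:
            if not _sequence_adjacent(ka, kb):
                continue
            first, second = (ka, kb) if ka.residue_number < kb.residue_number else (kb, ka)
            for lbl1, c1 in per_res[first].items():
                for lbl2, c2 in per_res[second].items():
                    if not _altloc_compatible(lbl1, lbl2):
                        continue
                    for names, ideal in table.link_bonds.items():
                        n1, n2 = names.split("-")
                        if n1 in c1 and n2 in c2:
                            d = np.linalg.norm(c1[n1].position - c2[n2].position)
                            bond_dev.append(float(d) - ideal)
                    for names, ideal in table.link_angles.items():
                        n1, n2, n3 = names.split("-")
                        # CA-C-N: first two atoms in residue i, N in i+1
                        if names == "CA-C-N" and n1 in c1 and n2 in c1 and n3 in c2:
                            angle_dev.append(_angle_deg(
                                c1[n1].position, c1[n2].position, c2[n3].position
                            ) - ideal)
                        # C-N-CA: C in residue i, last two in i+1
                        if names == "C-N-CA" and n1 in c1 and n2 in c2 and n3 in c2:
                            angle_dev.append(_angle_deg(
                                c1[n1].position, c2[n2].position, c2[n3].position
                            ) - ideal)

    rms_bond = float(np.sqrt(np.mean(np.square(bond_dev)))) if bond_dev else None
    rms_angle = float(np.sqrt(np.mean(np.square(angle_dev)))) if angle_dev else None
    return rms_bond, rms_angle, len(bond_dev), len(angle_dev)


# ---------------------------------------------------------------------------
# Conformer A vs B RMSD
# ---------------------------------------------------------------------------

def conformer_rmsd(
    model: StructureModel,
    selection: ResidueSelection,
    labels: Tuple[str, str] = ("A", "B"),
) -> float:
    """RMSD between same-named atoms of the two conformers, no re-superposition."""
    char_a, char_b = labels
    sq = []
    missing: List[str] = []
    for key, atoms in model.residues.items():
        if key not in selection:
            continue
        pos_a = {a.atom_name: a.position for a in atoms if a.altloc == char_a}
        pos_b = {a.atom_name: a.position for a in atoms if a.altloc == char_b}
        if not pos_a or not pos_b:
            missing.append(f"{key}: missing conformer "
                           f"{char_a if not pos_a else char_b}")
            continue
        for name, pb in pos_b.items():
            if name not in pos_a:
                missing.append(f"{key}:{name} has no {char_a} partner")
                continue
            sq.append(float(np.sum((pos_a[name] - pb) ** 2)))
    if missing:
        raise ValidationError("conformer_rmsd: unpaired atoms: " + "; ".join(missing))
    if not sq:
        raise ValidationError("conformer_rmsd: no paired atoms in selection")
    return float(np.sqrt(np.mean(sq)))
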