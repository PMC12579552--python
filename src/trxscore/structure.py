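"""Atomic structure handling with altloc/occupancy/B-factor semantics.

Structures are held as ordered residue groups of atom records in an
orthogonal-angstrom frame.  PDB reading and writing is delegated to gemmi;
a fixed-column pre-validation pass reports malformed ATOM/HETATM records
with their line numbers, since gemmi zero-fills unparsable numeric fields
instead of failing.

Two-state (reference + triggered) models are produced by
:func:`merge_alt_conformers`: the reference copy of each selected residue
becomes conformer A, the candidate conformer becomes B, occupancies are
complementary and B-factors of conformer B are copied from the same-named
A atoms — the convention used when a low-occupancy triggered state is
modeled on top of a dominant resting state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "ResidueSelection",
    "RigidTransform",
    "StructureModel",
    "ParseError",
    "ValidationError",
    "read_structure",
    "write_structure",
    "superpose_calpha",
    "apply_transform",
    "map_atom_names",
    "merge_alt_conformers",
]

#: electrons per neutral element (amplitude of the model density Gaussian)
ELECTRON_COUNT = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "ZN": 30,
    "SE": 34, "BR": 35, "I": 53,
}


class ParseError(ValueError):
    """A PDB record could not be parsed."""


class ValidationError(ValueError):
    """A structure violates an invariant (duplicate atoms, bad occupancy...)."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue: chain, number, insertion code and name."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    @property
    def site(self) -> Tuple[str, int, str]:
        """Position-only identity (chain, number, icode), ignoring the name."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    def __str__(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.residue_number}{icode}:{self.residue_name}"


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    position: np.ndarray  # (3,) float, orthogonal angstroms
    altloc: str = ""  # single char or "" (blank)
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(f"atom {self.atom_name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.atom_name}: non-finite position")
        if not (0.0 <= self.occupancy <= 1.0 + 1e-9):
            raise ValidationError(
                f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.b_factor < 0:
            raise ValidationError(f"atom {self.atom_name}: negative B-factor")

    @property
    def electron_count(self) -> float:
        try:
            return float(ELECTRON_COUNT[self.element.upper()])
        except KeyError:
            raise ValidationError(f"unknown element {self.element!r}") from None

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return AtomRecord(
            atom_name=self.atom_name,
            element=self.element,
            position=self.position.copy(),
            altloc=self.altloc,
            occupancy=self.occupancy,
            b_factor=self.b_factor,
        )


@dataclass(frozen=True)
class ResidueSelection:
    """Set of residues addressed by (chain, number, icode) site."""

    sites: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_keys(cls, keys: Iterable[ResidueKey]) -> "ResidueSelection":
        return cls(frozenset(k.site for k in keys))

    @classmethod
    def from_string(cls, text: str) -> "ResidueSelection":
        """Parse ``"A:12,A:13"`` style selections (chain:resnum[icode])."""
        sites = set()
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            chain, _, res = token.partition(":")
            if not res:
                raise ValueError(f"bad selection token {token!r}; expected chain:resnum")
            icode = ""
            if res and res[-1].isalpha():
                res, icode = res[:-1], res[-1]
            sites.add((chain, int(res), icode))
        return cls(frozenset(sites))

    def __contains__(self, key: ResidueKey) -> bool:
        return key.site in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(sorted(self.sites))


@dataclass
class RigidTransform:
    """Proper rigid motion r -> R @ r + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-9):
            raise ValidationError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)


@dataclass
class StructureModel:
    """Ordered residues -> atom lists, plus crystal frame metadata."""

    residues: Dict[ResidueKey, List[AtomRecord]] = field(default_factory=dict)
    unit_cell: Tuple[float, float, float, float, float, float] = (
        1.0, 1.0, 1.0, 90.0, 90.0, 90.0,
    )
    space_group: str = "P 1"

    # -- iteration helpers -------------------------------------------------
    def iter_atoms(self) -> Iterator[Tuple[ResidueKey, AtomRecord]]:
        for key, atoms in self.residues.items():
            for atom in atoms:
                yield key, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(a) for a in self.residues.values())

    def coordinates(self) -> np.ndarray:
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.position for _, a in self.iter_atoms()])

    def get_residue(self, key: ResidueKey) -> List[AtomRecord]:
        return self.residues[key]

    def find_site(self, site: Tuple[str, int, str]) -> Optional[ResidueKey]:
        for key in self.residues:
            if key.site == site:
                return key
        return None

    def copy(self) -> "StructureModel":
        return StructureModel(
            residues={k: [a.copy() for a in atoms] for k, atoms in self.residues.items()},
            unit_cell=tuple(self.unit_cell),
            space_group=self.space_group,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check altloc uniqueness and occupancy complement invariants."""
        for key, atoms in self.residues.items():
            seen = set()
            by_name: Dict[str, Dict[str, float]] = {}
            for atom in atoms:
                ident = (atom.atom_name, atom.altloc)
                if ident in seen:
                    raise ValidationError(
                        f"residue {key}: duplicate atom {atom.atom_name!r} "
                        f"with altloc {atom.altloc!r}"
                    )
                seen.add(ident)
                by_name.setdefault(atom.atom_name, {})[atom.altloc] = atom.occupancy
            for name, alts in by_name.items():
                if "A" in alts and "B" in alts:
                    total = alts["A"] + alts["B"]
                    if abs(total - 1.0) > 1e-6:
                        raise ValidationError(
                            f"residue {key} atom {name}: occ(A)+occ(B)={total:.8f} != 1"
                        )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: str) -> None:
    """Raise ParseError (with line number) on malformed ATOM/HETATM records."""
    numeric_fields = [(30, 38), (38, 46), (46, 54), (54, 60), (60, 66)]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: truncated ATOM/HETATM record")
            for start, stop in numeric_fields:
                text = line[start:stop].strip()
                if not text and start >= 54:
                    continue  # occupancy/B may be blank; default applied
                try:
                    float(text)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable numeric field "
                        f"{text!r} in columns {start + 1}-{stop}"
                    ) from None
            try:
                int(line[22:26].strip())
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparsable residue number {line[22:26]!r}"
                ) from None


def read_structure(path: str, dialect: str = "pdb") -> StructureModel:
    """Read a PDB file, preserving altloc, occupancy and B-factor columns."""
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'pdb' in v1")
    _prevalidate_pdb(str(path))
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    model = StructureModel(
        unit_cell=(
            st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma,
        ),
        space_group=st.spacegroup_hm or "P 1",
    )
    gm = st[0]
    for chain in gm:
        for res in chain:
            key = ResidueKey(
                chain_id=chain.name,
                residue_number=res.seqid.num,
                insertion_code=(res.seqid.icode or " ").strip(),
                residue_name=res.name,
            )
            atoms = model.residues.setdefault(key, [])
            for atom in res:
                atoms.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        altloc=(atom.altloc or "").strip("\x00").strip(),
                        occupancy=atom.occ,
                        b_factor=atom.b_iso,
                    )
                )
    model.validate()
    return model


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.unit_cell)
    st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    chains: Dict[str, gemmi.Chain] = {}
    for key, atoms in model.residues.items():
        chain = chains.get(key.chain_id)
        if chain is None:
            chain = gemmi.Chain(key.chain_id)
            chains[key.chain_id] = chain
        res = gemmi.Residue()
        res.name = key.residue_name
        res.seqid = gemmi.SeqId(key.residue_number, key.insertion_code or " ")
        res.het_flag = "A"
        for atom in atoms:
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.altloc = atom.altloc if atom.altloc else "\x00"
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_factor
            res.add_atom(ga)
        chain.add_residue(res)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    return st


def write_structure(model: StructureModel, path: str) -> None:
    """Write a PDB file (fixed columns; coords %8.3f, occ/B %6.2f)."""
    model.validate()
    _to_gemmi(model).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _matched_calpha(
    mobile: StructureModel,
    reference: StructureModel,
    selection: Optional[ResidueSelection],
) -> Tuple[np.ndarray, np.ndarray]:
    ref_ca = {}
    for key, atoms in reference.residues.items():
        if selection is not None and key not in selection:
            continue
        for atom in atoms:
            if atom.atom_name == "CA" and atom.element.upper() == "C":
                ref_ca[key.site] = atom.position
                break
    mob, ref = [], []
    for key, atoms in mobile.residues.items():
        if key.site not in ref_ca:
            continue
        ca = next(
            (a for a in atoms if a.atom_name == "CA" and a.element.upper() == "C"),
            None,
        )
        if ca is None:
            logger.warning("superpose: residue %s has no CA in mobile; skipped", key)
            continue
        mob.append(ca.position)
        ref.append(ref_ca[key.site])
    return np.array(mob), np.array(ref)


def superpose_calpha(
    mobile: StructureModel,
    reference: StructureModel,
    selection: Optional[ResidueSelection] = None,
) -> Tuple[RigidTransform, float]:
    """Least-squares (Kabsch) rigid superposition of mobile CA onto reference CA.

    Returns the optimal transform and the post-fit CA RMSD.  The mobile model
    is not modified; use :func:`apply_transform` to get the moved copy.
    """
    mob, ref = _matched_calpha(mobile, reference, selection)
    if len(mob) < 3:
        raise ValidationError(
            f"superposition needs >=3 matched CA pairs, found {len(mob)}"
        )
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear point sets leave the rotation about the line undetermined
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValidationError("superposition: CA positions are (near-)collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rmat = rot.as_matrix()
    trans = ref.mean(axis=0) - rmat @ mob.mean(axis=0)
    transform = RigidTransform(rmat, trans)
    moved = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(model: StructureModel, transform: RigidTransform) -> StructureModel:
    """Return a copy of the model with the rigid transform applied to all atoms."""
    out = model.copy()
    for _, atom in out.iter_atoms():
        atom.position = transform.apply(atom.position)
    return out


# ---------------------------------------------------------------------------
# Atom-name mapping and two-state merging
# ---------------------------------------------------------------------------

def map_atom_names(
    fragment: StructureModel,
    mapping: Sequence[Tuple[str, str, str]],
) -> Tuple[StructureModel, int]:
    """Rename atoms per (residue_name, from_name, to_name) rules.

    Only atom_name fields change; unmapped names pass through.  Returns the
    renamed model and the number of atoms renamed.  A mapping that collides
    two atoms of one residue into the same name is an error.
    """
    rules: Dict[Tuple[str, str], str] = {}
    for resname, from_name, to_name in mapping:
        rule_key = (resname, from_name)
        if rule_key in rules and rules[rule_key] != to_name:
            raise ValidationError(f"ambiguous mapping for {rule_key}")
        rules[rule_key] = to_name
    out = fragment.copy()
    n_renamed = 0
    for key, atoms in out.residues.items():
        for atom in atoms:
            to_name = rules.get((key.residue_name, atom.atom_name))
            if to_name is None:
                to_name = rules.get(("*", atom.atom_name))
            if to_name is not None and to_name != atom.atom_name:
                atom.atom_name = to_name
                n_renamed += 1
        names = [(a.atom_name, a.altloc) for a in atoms]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"mapping collides atoms into a duplicate name in residue {key}"
            )
    if n_renamed:
        logger.info("map_atom_names: renamed %d atoms", n_renamed)
    return out, n_renamed


def merge_alt_conformers(
    reference: StructureModel,
    fragment: StructureModel,
    selection: ResidueSelection,
    q_init: float = 0.25,
    labels: Tuple[str, str] = ("A", "B"),
    keep_hydrogens: bool = False,
) -> StructureModel:
    """Merge a candidate conformer into the reference as a two-state model.

    For each selected residue the reference atoms become conformer
    ``labels[0]`` at occupancy ``1 - q_init`` and the fragment atoms become
    conformer ``labels[1]`` at occupancy ``q_init``; each B atom inherits the
    B-factor of the same-named reference atom.  Unselected residues are left
    untouched (blank altloc).  Fragment hydrogens are dropped unless
    ``keep_hydrogens`` is set.
    """
    if not (0.0 < q_init < 1.0):
        raise ValidationError(f"q_init must be in (0, 1), got {q_init}")
    if len(selection) == 0:
        raise ValidationError("selection is empty")
    char_a, char_b = labels

    frag_by_site = {key.site: (key, atoms) for key, atoms in fragment.residues.items()}

    out = StructureModel(unit_cell=tuple(reference.unit_cell),
                         space_group=reference.space_group)
    n_merged = 0
    for key, atoms in reference.residues.items():
        if key not in selection:
            out.residues[key] = [a.copy() for a in atoms]
            continue
        if key.site not in frag_by_site:
            raise ValidationError(f"selected residue {key} missing from fragment")
        frag_key, frag_atoms = frag_by_site[key.site]
        if frag_key.residue_name != key.residue_name:
            raise ValidationError(
                f"residue {key.site} name mismatch: reference {key.residue_name!r} "
                f"vs fragment {frag_key.residue_name!r}"
            )
        ref_b_by_name = {a.atom_name: a.b_factor for a in atoms if not a.is_hydrogen}
        merged: List[AtomRecord] = []
        for atom in atoms:
            a = atom.copy()
            a.altloc = char_a
            a.occupancy = 1.0 - q_init
            merged.append(a)
        missing = []
        for atom in frag_atoms:
            if atom.is_hydrogen and not keep_hydrogens:
                continue
            if atom.atom_name not in ref_b_by_name:
                missing.append(atom.atom_name)
                continue
            b = atom.copy()
            b.altloc = char_b
            b.occupancy = q_init
            b.b_factor = ref_b_by_name[atom.atom_name]
            merged.append(b)
        if missing:
            raise ValidationError(
                f"residue {key}: fragment atoms {missing} have no same-named "
                "reference atom (B-factor source undefined)"
            )
        out.residues[key] = merged
        n_merged += 1
    # every selected site must have been found in the reference
    ref_sites = {k.site for k in reference.residues}
    unresolved = [s for s in selection.sites if s not in ref_sites]
    if unresolved:
        raise ValidationError(f"selection sites absent from reference: {unresolved}")
    out.validate()
    logger.info("merged %d residues as alternative conformers (q_init=%.3f)",
                n_merged, q_init)
    return out
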