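"""Synthetic two-state datasets for exercising the whole pipeline at desk scale.

The generator emulates the data regime of a pump-probe crystallography
experiment in which only a fraction q of the molecules reach the triggered
state: the "observed" triggered map is an occupancy-weighted mixture

    map_trig = (1 - q) * rho_A + q * rho_B + noise

of the reference conformer density rho_A and a displaced truth conformer
density rho_B, with i.i.d. Gaussian voxel noise scaled to a fraction of the
reference map RMS.  A decoy ensemble stands in for conformers sampled from
molecular dynamics: a few frames are the planted truth plus a small jitter,
the rest are perturbed copies of the reference.  A closed-form least-squares
occupancy refiner stands in for external reciprocal-space refinement (which
adjusts coordinates as well; the mock adjusts occupancy only).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .density import DensityGrid, GridSpec, compute_model_density, difference_grid
from .ensemble import FrameSet
from .geometry import IdealGeometryTable
from .structure import (
    AtomRecord,
    ResidueKey,
    ResidueSelection,
    StructureModel,
    ValidationError,
)

__all__ = [
    "SimulationSpec",
    "SyntheticDataset",
    "make_toy_structure",
    "make_truth_conformer",
    "make_decoy_ensemble",
    "simulate_two_state_maps",
    "make_dataset",
    "mock_refine_occupancy",
]

# torsion angles (deg) defining the backbone motifs
MOTIF_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}
OMEGA = 180.0  # trans peptide
#: improper torsion C-N-CA-CB placing CB with L-amino-acid chirality
CB_TORSION = -122.6


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic two-state dataset."""

    n_residues: int = 20
    motif: str = "helix"
    spacing: float = 0.8          # grid spacing, A
    margin: float = 4.0           # grid margin around the model, A
    selection: Optional[ResidueSelection] = None  # default: 3 central residues
    q_true: float = 0.25          # triggered-state occupancy
    noise: float = 0.05           # voxel noise as a fraction of ref map RMS
    n_decoys: int = 200
    n_near: int = 10              # near-truth decoys among n_decoys
    near_scale: float = 0.05      # per-atom jitter of near decoys, A
    far_scale: float = 0.8        # per-atom perturbation of far decoys, A
    truth_shift: float = 1.2      # rigid displacement of the truth conformer, A
    b_factor: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.q_true < 1.0):
            raise ValidationError("q_true must be in (0, 1)")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")
        if self.n_near > self.n_decoys:
            raise ValidationError("n_near cannot exceed n_decoys")

    def resolve_selection(self, model: StructureModel) -> ResidueSelection:
        if self.selection is not None:
            return self.selection
        keys = list(model.residues)
        mid = len(keys) // 2
        return ResidueSelection.from_keys(keys[max(0, mid - 1): mid + 2])


@dataclass
class SyntheticDataset:
    reference: StructureModel
    truth: StructureModel
    frames: FrameSet
    map_ref: DensityGrid
    map_trig: DensityGrid
    diff: DensityGrid
    rho_A: DensityGrid
    rho_B: DensityGrid
    grid_spec: GridSpec
    selection: ResidueSelection
    manifest: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy structure construction (NeRF internal-coordinate build)
# ---------------------------------------------------------------------------

def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d.

    d is at distance ``bond`` from c, with angle b-c-d and dihedral a-b-c-d.
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_toy_structure(
    n_residues: int,
    motif: str = "helix",
    seed: int = 0,
    b_factor: float = 20.0,
    chain_id: str = "A",
) -> StructureModel:
    """Ideal-geometry poly-alanine backbone + CB in a helix or strand motif.

    All bond lengths and angles come from the packaged ideal-geometry table,
    so the structure scores zero bond/angle RMS and zero clashscore by
    construction.  Deterministic for a given seed (the seed is recorded for
    manifest uniformity; the ideal build has no random component).
    """
    if n_residues < 3:
        raise ValidationError("need at least 3 residues")
    if motif not in MOTIF_TORSIONS:
        raise ValueError(f"unknown motif {motif!r}")
    phi, psi = MOTIF_TORSIONS[motif]
    table = IdealGeometryTable.load_default()
    b = table.residue_bonds("ALA")
    a = table.residue_angles("ALA")
    link_b = table.link_bonds["C-N"]
    ang_CACN = table.link_angles["CA-C-N"]
    ang_CNCA = table.link_angles["C-N-CA"]

    # first residue: N at origin, CA on x, C in the xy-plane
    n_pos = np.zeros(3)
    ca_pos = np.array([b["N-CA"], 0.0, 0.0])
    theta = math.radians(a["N-CA-C"])
    c_pos = ca_pos + b["CA-C"] * np.array([-math.cos(theta), math.sin(theta), 0.0])

    backbone: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = [
        (n_pos, ca_pos, c_pos)
    ]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = _place_atom(n_prev, ca_prev, c_prev, link_b, ang_CACN, psi)
        ca_next = _place_atom(ca_prev, c_prev, n_next, b["N-CA"], ang_CNCA, OMEGA)
        c_next = _place_atom(c_prev, n_next, ca_next, b["CA-C"], a["N-CA-C"], phi)
        backbone.append((n_next, ca_next, c_next))

    model = StructureModel()
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        resnum = i + 1
        key = ResidueKey(chain_id, resnum, "", "ALA")
        # carbonyl O opposite the next N about the CA-C axis
        o_i = _place_atom(n_i, ca_i, c_i, b["C-O"], a["CA-C-O"], psi + 180.0)
        cb_i = _place_atom(c_i, n_i, ca_i, b["CA-CB"], a["N-CA-CB"], CB_TORSION)
        atoms = [
            AtomRecord("N", "N", n_i, "", 1.0, b_factor),
            AtomRecord("CA", "C", ca_i, "", 1.0, b_factor),
            AtomRecord("C", "C", c_i, "", 1.0, b_factor),
            AtomRecord("O", "O", o_i, "", 1.0, b_factor),
            AtomRecord("CB", "C", cb_i, "", 1.0, b_factor),
        ]
        model.residues[key] = atoms
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Truth conformer and decoy ensemble
# ---------------------------------------------------------------------------

def make_truth_conformer(
    reference: StructureModel,
    selection: ResidueSelection,
    shift: float = 1.2,
    seed: int = 0,
) -> StructureModel:
    """Planted triggered-state conformer: selected residues rigidly displaced.

    The displacement direction is drawn deterministically from the seed; the
    magnitude is ``shift``.  A rigid move keeps the conformer internally
    ideal, mimicking a coherent side-of-helix motion.
    """
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    out = reference.copy()
    moved = 0
    for key, atoms in out.residues.items():
        if key not in selection:
            continue
        for atom in atoms:
            atom.position = atom.position + shift * direction
        moved += 1
    if moved == 0:
        raise ValidationError("truth conformer: selection matched no residues")
    return out


def _perturb_selected(
    model: StructureModel,
    selection: ResidueSelection,
    scale: float,
    rng: np.random.Generator,
) -> StructureModel:
    out = model.copy()
    for key, atoms in out.residues.items():
        if key not in selection:
            continue
        for atom in atoms:
            atom.position = atom.position + rng.normal(0.0, scale, size=3)
    return out


def _selected_rmsd(
    a: StructureModel, b: StructureModel, selection: ResidueSelection
) -> float:
    sq = []
    b_pos = {
        (key.site, atom.atom_name): atom.position
        for key, atom in b.iter_atoms() if key in selection
    }
    for key, atom in a.iter_atoms():
        if key not in selection:
            continue
        sq.append(float(np.sum(
            (atom.position - b_pos[(key.site, atom.atom_name)]) ** 2
        )))
    return float(np.sqrt(np.mean(sq)))


def make_decoy_ensemble(
    reference: StructureModel,
    truth: StructureModel,
    selection: ResidueSelection,
    spec: SimulationSpec,
) -> Tuple[FrameSet, Dict]:
    """Decoy conformer pool with a planted truth.

    ``n_near`` frames are the truth plus per-atom Gaussian jitter at the near
    scale; the remaining frames are the reference perturbed per atom at the
    far scale.  The manifest records each frame's class and its RMSD to the
    planted truth over the selected residues.
    """
    rng = np.random.default_rng(spec.seed)
    classes = np.array(
        ["near"] * spec.n_near + ["far"] * (spec.n_decoys - spec.n_near)
    )
    rng.shuffle(classes)
    frames: List[StructureModel] = []
    records = []
    for i, cls in enumerate(classes):
        if cls == "near":
            frame = _perturb_selected(truth, selection, spec.near_scale, rng)
        else:
            frame = _perturb_selected(reference, selection, spec.far_scale, rng)
        frames.append(frame)
        records.append({
            "frame_id": f"frame_{i:04d}",
            "class": str(cls),
            "rmsd_to_truth": _selected_rmsd(frame, truth, selection),
        })
    manifest = {
        "seed": spec.seed,
        "n_decoys": spec.n_decoys,
        "n_near": spec.n_near,
        "near_scale": spec.near_scale,
        "far_scale": spec.far_scale,
        "frames": records,
    }
    frame_set = FrameSet(frames, [r["frame_id"] for r in records])
    return frame_set, manifest


# ---------------------------------------------------------------------------
# Two-state mixture maps
# ---------------------------------------------------------------------------

def simulate_two_state_maps(
    reference: StructureModel,
    truth: StructureModel,
    spec: SimulationSpec,
    grid_spec: Optional[GridSpec] = None,
) -> Tuple[DensityGrid, DensityGrid, DensityGrid, DensityGrid, DensityGrid, GridSpec]:
    """Reference and triggered maps as an occupancy-weighted mixture plus noise.

    map_ref  = rho_A + eps1,
    map_trig = (1 - q) rho_A + q rho_B + eps2,

    with eps i.i.d. normal per voxel, sigma = spec.noise x RMS(rho_A), drawn
    independently for the two maps.  Returns (map_ref, map_trig, diff, rho_A,
    rho_B, grid_spec); with zero noise, diff == q (rho_B - rho_A) exactly up
    to floating point.
    """
    ref_ids = {(k.site, a.atom_name) for k, a in reference.iter_atoms()}
    tru_ids = {(k.site, a.atom_name) for k, a in truth.iter_atoms()}
    if ref_ids != tru_ids:
        raise ValidationError("reference and truth atom inventories differ")
    if grid_spec is None:
        coords = np.vstack([reference.coordinates(), truth.coordinates()])
        lo = coords.min(axis=0) - spec.margin
        hi = coords.max(axis=0) + spec.margin
        grid_spec = GridSpec(
            cell=tuple(float(x) for x in (hi - lo)),
            spacing=(spec.spacing,) * 3,
            origin=tuple(float(x) for x in lo),
        )
    rho_a = compute_model_density(reference, grid_spec)
    rho_b = compute_model_density(truth, grid_spec)
    rng = np.random.default_rng(spec.seed)
    sigma_noise = spec.noise * float(np.std(rho_a.values))
    eps1 = rng.normal(0.0, sigma_noise, rho_a.shape) if sigma_noise > 0 else 0.0
    eps2 = rng.normal(0.0, sigma_noise, rho_a.shape) if sigma_noise > 0 else 0.0
    map_ref = DensityGrid(rho_a.values + eps1, rho_a.spacing, rho_a.origin.copy())
    mix = (1.0 - spec.q_true) * rho_a.values + spec.q_true * rho_b.values
    map_trig = DensityGrid(mix + eps2, rho_a.spacing, rho_a.origin.copy())
    diff = difference_grid(map_trig, map_ref)
    return map_ref, map_trig, diff, rho_a, rho_b, grid_spec


def make_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Full synthetic study: reference, truth, decoys, mixture maps, manifest."""
    reference = make_toy_structure(
        spec.n_residues, spec.motif, spec.seed, spec.b_factor
    )
    selection = spec.resolve_selection(reference)
    truth = make_truth_conformer(
        reference, selection, shift=spec.truth_shift, seed=spec.seed
    )
    frames, manifest = make_decoy_ensemble(reference, truth, selection, spec)
    map_ref, map_trig, diff, rho_a, rho_b, grid_spec = simulate_two_state_maps(
        reference, truth, spec
    )
    manifest = dict(manifest)
    manifest["spec"] = {
        k: (v if not isinstance(v, ResidueSelection) else sorted(v.sites))
        for k, v in asdict(spec).items()
    }
    manifest["selection"] = sorted(selection.sites)
    return SyntheticDataset(
        reference=reference,
        truth=truth,
        frames=frames,
        map_ref=map_ref,
        map_trig=map_trig,
        diff=diff,
        rho_A=rho_a,
        rho_B=rho_b,
        grid_spec=grid_spec,
        selection=selection,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Mock occupancy refinement
# ---------------------------------------------------------------------------

def mock_refine_occupancy(
    merged: StructureModel,
    map_trig: DensityGrid,
    rho_a: DensityGrid,
    rho_b: DensityGrid,
    labels: Tuple[str, str] = ("A", "B"),
) -> Tuple[float, StructureModel]:
    """Closed-form least-squares group occupancy against the triggered map.

    Solves q_hat = argmin_q sum_voxels (map_trig - (1-q) rho_A - q rho_B)^2,
    i.e. q_hat = <map_trig - rho_A, rho_B - rho_A> / |rho_B - rho_A|^2,
    clamped to [0, 1], and returns the merged model with occupancies set to
    (1 - q_hat, q_hat) on the two conformers.  Coordinates are not moved —
    coordinate refinement is the externalized step.
    """
    if not (map_trig.same_geometry(rho_a) and map_trig.same_geometry(rho_b)):
        raise ValidationError("mock refiner: grid geometries differ")
    e = rho_b.values - rho_a.values
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValidationError(
            "mock refiner: conformer densities identical; occupancy unidentifiable"
        )
    num = float(np.sum((map_trig.values - rho_a.values) * e))
    q_hat = min(1.0, max(0.0, num / denom))
    char_a, char_b = labels
    refined = merged.copy()
    for _, atom in refined.iter_atoms():
        if atom.altloc == char_a:
            atom.occupancy = 1.0 - q_hat
        elif atom.altloc == char_b:
            atom.occupancy = q_hat
    return q_hat, refined
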