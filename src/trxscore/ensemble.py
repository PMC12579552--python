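"""Ensemble heterogeneity analysis: RMSF profiles and before/after RMSD.

Fluctuations are computed on the frames exactly as given — the pipeline
superposes frames onto the reference before calling in here, and adding a
per-frame rigid motion changes the result by design.  Per-atom RMSF is

    rmsf_i = sqrt( (1/N) sum_n |r_{i,n} - rbar_i|^2 )

and the per-residue value aggregates atomic RMSFs as an RMS,

    rmsf_res = sqrt( (1/M) sum_i rmsf_i^2 )

(``agg="mean"`` gives the plain mean instead).  A per-residue stability flag
marks profiles below 1.0 A, the conventional bound for a stably refined
coordinate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure import ResidueKey, ResidueSelection, StructureModel, ValidationError

__all__ = [
    "FrameSet",
    "RMSFProfile",
    "atomic_rmsf",
    "residue_rmsf",
    "before_after_rmsd",
    "STABILITY_THRESHOLD",
]

#: per-residue RMSF below this (A) marks a stably refined region
STABILITY_THRESHOLD = 1.0

AtomId = Tuple[ResidueKey, str, str]  # (residue, atom_name, altloc)


@dataclass
class FrameSet:
    """N aligned conformations sharing one atom inventory."""

    frames: List[StructureModel]
    frame_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frame_ids:
            self.frame_ids = [f"frame_{i:04d}" for i in range(len(self.frames))]
        if len(self.frame_ids) != len(self.frames):
            raise ValidationError("frame_ids length != number of frames")

    def __len__(self) -> int:
        return len(self.frames)

    def atom_ids(self) -> List[AtomId]:
        return [
            (key, a.atom_name, a.altloc)
            for key, a in self.frames[0].iter_atoms()
        ]

    def coordinate_array(
        self, selection: Optional[ResidueSelection] = None
    ) -> Tuple[np.ndarray, List[AtomId]]:
        """(N, n_atoms, 3) array over a common (optionally selected) inventory."""
        ref_ids = [
            i for i in self.atom_ids()
            if selection is None or i[0] in selection
        ]
        if not ref_ids:
            raise ValidationError("no atoms match the selection")
        coords = np.empty((len(self.frames), len(ref_ids), 3))
        for n, frame in enumerate(self.frames):
            lookup = {
                (key, a.atom_name, a.altloc): a.position
                for key, a in frame.iter_atoms()
            }
            missing = [i for i in ref_ids if i not in lookup]
            if missing:
                raise ValidationError(
                    f"frame {self.frame_ids[n]} missing atoms: "
                    + ", ".join(f"{k}:{nm}" for k, nm, _ in missing[:5])
                    + ("..." if len(missing) > 5 else "")
                )
            coords[n] = [lookup[i] for i in ref_ids]
        return coords, ref_ids


@dataclass
class RMSFProfile:
    atom_ids: List[AtomId]
    atomic: np.ndarray  # per-atom RMSF, A
    mean_positions: np.ndarray  # (n_atoms, 3)
    residue_keys: List[ResidueKey]
    residue: np.ndarray  # per-residue RMSF, A
    atom_counts: np.ndarray  # M per residue
    stable: np.ndarray  # residue RMSF < 1.0 A

    def as_rows(self):
        for key, val, m, st in zip(
            self.residue_keys, self.residue, self.atom_counts, self.stable
        ):
            yield key, float(val), int(m), bool(st)


def atomic_rmsf(
    frames: FrameSet, selection: Optional[ResidueSelection] = None
) -> Tuple[np.ndarray, List[AtomId], np.ndarray]:
    """Per-atom RMSF over N >= 2 pre-aligned frames.

    Returns (rmsf values, atom ids, mean positions).
    """
    if len(frames) < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    coords, ids = frames.coordinate_array(selection)
    mean_pos = coords.mean(axis=0)
    disp2 = np.sum((coords - mean_pos[None]) ** 2, axis=2)
    rmsf = np.sqrt(disp2.mean(axis=0))
    return rmsf, ids, mean_pos


def residue_rmsf(
    atomic: np.ndarray,
    atom_ids: Sequence[AtomId],
    mean_positions: Optional[np.ndarray] = None,
    agg: str = "rms",
) -> RMSFProfile:
    """Aggregate atomic RMSFs per residue (RMS by default, or plain mean)."""
    if agg not in ("rms", "mean"):
        raise ValueError(f"agg must be 'rms' or 'mean', got {agg!r}")
    order: List[ResidueKey] = []
    groups: Dict[ResidueKey, List[int]] = {}
    for i, (key, _, _) in enumerate(atom_ids):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    res_vals = np.empty(len(order))
    counts = np.empty(len(order), dtype=int)
    for r, key in enumerate(order):
        vals = atomic[groups[key]]
        counts[r] = len(vals)
        if agg == "rms":
            res_vals[r] = np.sqrt(np.mean(vals**2))
        else:
            res_vals[r] = np.mean(vals)
    if mean_positions is None:
        mean_positions = np.zeros((len(atom_ids), 3))
    return RMSFProfile(
        atom_ids=list(atom_ids),
        atomic=np.asarray(atomic, dtype=float),
        mean_positions=mean_positions,
        residue_keys=order,
        residue=res_vals,
        atom_counts=counts,
        stable=res_vals < STABILITY_THRESHOLD,
    )


def before_after_rmsd(
    pairs: Sequence[Tuple[StructureModel, StructureModel]],
    selection: Optional[ResidueSelection] = None,
) -> np.ndarray:
    """Coordinate RMSD per (input, refined) pair over selected atoms.

    No re-superposition is performed; atoms are matched by
    (residue, atom_name, altloc) and a mismatch is an error.
    """
    out = np.empty(len(pairs))
    for n, (before, after) in enumerate(pairs):
        before_pos = {
            (key, a.atom_name, a.altloc): a.position
            for key, a in before.iter_atoms()
            if selection is None or key in selection
        }
        if not before_pos:
            raise ValidationError("no atoms match the selection")
        sq = []
        after_pos = {
            (key, a.atom_name, a.altloc): a.position
            for key, a in after.iter_atoms()
        }
        missing = [i for i in before_pos if i not in after_pos]
        if missing:
            raise ValidationError(
                f"pair {n}: refined frame missing atoms "
                + ", ".join(f"{k}:{nm}" for k, nm, _ in missing[:5])
            )
        for ident, pos in before_pos.items():
            sq.append(float(np.sum((after_pos[ident] - pos) ** 2)))
        out[n] = np.sqrt(np.mean(sq))
    return out


def rmsf_to_bfactor_model(profile: RMSFProfile, model: StructureModel) -> StructureModel:
    """Copy of the model with atomic RMSF written into the B-factor column."""
    out = model.copy()
    lookup = {i: v for i, v in zip(profile.atom_ids, profile.atomic)}
    for key, atom in out.iter_atoms():
        ident = (key, atom.atom_name, atom.altloc)
        if ident in lookup:
            atom.b_factor = float(lookup[ident])
    return out
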