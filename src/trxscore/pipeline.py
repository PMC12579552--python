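"""Batch orchestration: prepare, refine, measure, weight, score, rank.

Runs the full two-state modeling workflow over a pool of candidate frames:
each frame is superposed onto the reference on C-alpha atoms, merged as
conformer B at the initial occupancy, refined (mock occupancy refiner by
default, or an arbitrary external command), measured (mock real-space
R-factors, native geometry, per-residue density metrics), and the batch is
ranked by composite score.  Externally computed metric tables (refinement
logs, MolProbity summaries, EDSTATS per-residue statistics) can be ingested
to replace or complete the native values.

Per-frame failures are recorded and skipped — a large batch must survive
stragglers — and results are assembled keyed by frame id, so the final
ranking is independent of worker count.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
import math
import subprocess
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .density import (
    DensityGrid,
    GridSpec,
    ResidueDensityMetrics,
    ResidueWeightSet,
    compute_model_density,
    difference_grid,
    estimate_sigma,
    read_ccp4,
    residue_difference_weights,
    residue_mask,
    rscc,
    rszd,
    rszo,
)
from .geometry import bond_angle_rms, clashscore, conformer_rmsd
from .scoring import (
    GEOMETRY_COLUMNS,
    ModelMetrics,
    ScoreBreakdown,
    composite_score,
    rank_models,
)
from .simulate import mock_refine_occupancy
from .structure import (
    ResidueKey,
    ResidueSelection,
    StructureModel,
    ValidationError,
    apply_transform,
    merge_alt_conformers,
    read_structure,
    superpose_calpha,
    write_structure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "RefinerError",
    "select_frames",
    "ingest_external_metrics",
    "run_external_refiner",
    "run_batch_models",
    "run_batch",
]


class RefinerError(RuntimeError):
    """External refiner failed (nonzero exit, timeout, or missing output)."""


@dataclass
class PipelineConfig:
    """Configuration of a full batch run; defaults follow the workflow's
    standard conditions (q_init 25%, 2.0 A masks, 3 sigma weights)."""

    reference: str = ""
    frames: str = ""              # glob pattern
    output_dir: str = "trxscore_out"
    map_trig: str = ""            # observed triggered-state map (CCP4)
    map_ref: str = ""             # reference-state map (CCP4), for weights
    selection: str = ""           # "A:12,A:13" style
    skip_frames: int = 0
    q_init: float = 0.25
    mask_radius: float = 2.0
    z_threshold: float = 3.0
    capture_radius: float = 3.5
    sigma_method: str = "rms"
    refiner: str = "mock"         # "mock" or a command template with {model} {out}
    refiner_timeout: float = 600.0
    refine_log: str = ""          # optional ingested tables
    molprobity_table: str = ""
    edstats_table: str = ""
    prefer: str = ""              # "", "native" or "ingested" on conflicts
    workers: int = 1
    seed: int = 0
    resume: bool = False

    def validate_paths(self) -> None:
        for name in ("reference", "map_trig", "map_ref"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: Dict
    statuses: Dict[str, str] = field(default_factory=dict)  # frame id -> status
    provenance: Dict[str, Dict[str, str]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    version: str = __version__
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def select_frames(frame_ids: Sequence[str], skip_frames: int) -> List[str]:
    """Drop the leading ``skip_frames`` entries (early frames still biased
    toward the starting structure are conventionally discarded)."""
    if skip_frames < 0:
        raise ValueError("skip_frames must be >= 0")
    return list(frame_ids)[skip_frames:]


# ---------------------------------------------------------------------------
# External metric ingestion
# ---------------------------------------------------------------------------

_EDSTATS_COLUMNS = {"rscc", "rszo", "rszd_plus", "rszd_minus"}


def ingest_external_metrics(
    batch: Dict[str, ModelMetrics],
    refine_log: Optional[str] = None,
    molprobity_table: Optional[str] = None,
    edstats_table: Optional[str] = None,
    prefer: Optional[str] = None,
) -> None:
    """Populate ModelMetrics fields from external TSV tables (in place).

    Tables are tab-separated with a header; rows are matched to models by a
    ``model_id`` column.  Fields get provenance "ingested"; a clash with a
    native value raises unless ``prefer`` says which side wins.  Unknown
    columns are ignored with a warning; an unknown model id is an error.
    """

    def load(path: str) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t", comment="#")
        if "model_id" not in df.columns:
            raise ValidationError(f"{path}: no model_id column")
        bad = [str(i) for i in df["model_id"] if str(i) not in batch]
        if bad:
            raise ValidationError(f"{path}: unknown model ids {bad[:5]}")
        return df

    if refine_log:
        df = load(refine_log)
        for _, row in df.iterrows():
            m = batch[str(row["model_id"])]
            for col in ("r_work", "r_free"):
                if col in df.columns and not pd.isna(row[col]):
                    m.set_field(col, float(row[col]), "ingested", prefer)
    if molprobity_table:
        df = load(molprobity_table)
        known = set(GEOMETRY_COLUMNS)
        for col in df.columns:
            if col not in known and col != "model_id":
                logger.warning("molprobity table: ignoring unknown column %r", col)
        for _, row in df.iterrows():
            m = batch[str(row["model_id"])]
            for col in known & set(df.columns):
                if not pd.isna(row[col]):
                    m.set_field(col, float(row[col]), "ingested", prefer)
    if edstats_table:
        df = load(edstats_table)
        needed = {"chain", "resnum", "resname"} | _EDSTATS_COLUMNS
        missing = needed - set(df.columns)
        if missing:
            raise ValidationError(f"{edstats_table}: missing columns {sorted(missing)}")
        for lineno, row in df.iterrows():
            m = batch[str(row["model_id"])]
            key = ResidueKey(
                str(row["chain"]), int(row["resnum"]),
                str(row.get("icode", "") or ""), str(row["resname"]),
            )
            if key in m.residue_density and m.provenance.get(f"residue:{key}") != "ingested":
                if prefer is None:
                    raise ValidationError(
                        f"{m.model_id}/{key}: native and ingested residue metrics "
                        "conflict; pass --prefer"
                    )
                if prefer == "native":
                    continue
            try:
                m.residue_density[key] = ResidueDensityMetrics(
                    rscc=float(row["rscc"]),
                    rszo=float(row["rszo"]),
                    rszd_plus=float(row["rszd_plus"]),
                    rszd_minus=float(row["rszd_minus"]),
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{edstats_table}: malformed row {lineno + 2}: {exc}"
                ) from None
            m.provenance[f"residue:{key}"] = "ingested"


# ---------------------------------------------------------------------------
# External refiner contract
# ---------------------------------------------------------------------------

def run_external_refiner(
    command_template: str,
    model_path: str,
    out_path: str,
    data_args: str = "",
    timeout: float = 600.0,
) -> str:
    """Run an external refinement command and return the refined model path.

    The template must contain ``{model}`` and ``{out}`` placeholders;
    ``{data}`` is substituted with ``data_args`` verbatim (the workflow makes
    no assumption about the refiner's own flags).  Nonzero exit, timeout or a
    missing output file raise RefinerError.
    """
    if "{model}" not in command_template or "{out}" not in command_template:
        raise ValueError("refiner template must contain {model} and {out}")
    cmd = command_template.format(model=model_path, out=out_path, data=data_args)
    try:
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True, timeout=timeout
        )
    except subprocess.TimeoutExpired as exc:
        raise RefinerError(f"refiner timed out after {timeout}s: {cmd}") from exc
    log_path = Path(out_path).with_suffix(".log")
    log_path.write_text(
        f"$ {cmd}\n--- stdout ---\n{proc.stdout}\n--- stderr ---\n{proc.stderr}\n"
    )
    if proc.returncode != 0:
        raise RefinerError(f"refiner exited {proc.returncode}: {cmd}")
    if not Path(out_path).exists():
        raise RefinerError(f"refiner produced no output file: {out_path}")
    return out_path


# ---------------------------------------------------------------------------
# In-memory batch run
# ---------------------------------------------------------------------------

def _mock_r_factors(
    obs: DensityGrid, calc: DensityGrid, free_mask: np.ndarray
) -> Tuple[float, float]:
    """Real-space residual analog of R-work/R-free.

    R = sum|obs - calc| / sum|obs| over working (95%) and held-out free (5%)
    voxel subsets; the free subset is fixed per batch from the run seed.
    """
    resid = np.abs(obs.values - calc.values).ravel()
    denom = np.abs(obs.values).ravel()
    work = ~free_mask
    r_work = float(resid[work].sum() / denom[work].sum())
    r_free = float(resid[free_mask].sum() / denom[free_mask].sum())
    return min(r_work, 1.0), min(r_free, 1.0)


def _measure_frame(
    frame_id: str,
    frame: StructureModel,
    reference: StructureModel,
    selection: ResidueSelection,
    map_trig: DensityGrid,
    grid_spec: GridSpec,
    rho_rest: DensityGrid,
    rho_a_sel: DensityGrid,
    free_mask: np.ndarray,
    config: PipelineConfig,
) -> Tuple[ModelMetrics, StructureModel, float]:
    """prep -> refine (mock) -> measure for one candidate frame."""
    transform, _ = superpose_calpha(frame, reference)
    aligned = apply_transform(frame, transform)
    merged = merge_alt_conformers(
        reference, aligned, selection, q_init=config.q_init
    )
    rho_b_sel = compute_model_density(
        merged, grid_spec, altlocs={"B"}, occupancy_weighted=False
    )
    rho_a_full = DensityGrid(
        rho_rest.values + rho_a_sel.values, rho_rest.spacing, rho_rest.origin.copy()
    )
    rho_b_full = DensityGrid(
        rho_rest.values + rho_b_sel.values, rho_rest.spacing, rho_rest.origin.copy()
    )
    q_hat, refined = mock_refine_occupancy(merged, map_trig, rho_a_full, rho_b_full)

    calc = DensityGrid(
        rho_rest.values + (1.0 - q_hat) * rho_a_sel.values + q_hat * rho_b_sel.values,
        rho_rest.spacing,
        rho_rest.origin.copy(),
    )
    r_work, r_free = _mock_r_factors(map_trig, calc, free_mask)

    cs, _ = clashscore(refined)
    rms_bond, rms_angle, _, _ = bond_angle_rms(refined)
    rmsd_ab = conformer_rmsd(refined, selection)

    sigma_obs = estimate_sigma(map_trig, config.sigma_method)
    resid_grid = difference_grid(map_trig, calc)
    sigma_diff = estimate_sigma(resid_grid, config.sigma_method)
    residue_metrics: Dict[ResidueKey, ResidueDensityMetrics] = {}
    for key in refined.residues:
        if key not in selection:
            continue
        mask = residue_mask(
            refined, key, map_trig, radius=config.mask_radius, altlocs={"B"}
        )
        residue_metrics[key] = ResidueDensityMetrics(
            rscc=rscc(map_trig, calc, mask),
            rszo=rszo(map_trig, mask, sigma_obs),
            rszd_plus=rszd(resid_grid, mask, sigma_diff)[0],
            rszd_minus=rszd(resid_grid, mask, sigma_diff)[1],
        )

    metrics = ModelMetrics(
        model_id=frame_id,
        r_work=r_work,
        r_free=r_free,
        rms_bond=rms_bond,
        rms_angle=rms_angle,
        clashscore=cs,
        rmsd_AB=rmsd_ab,
        residue_density=residue_metrics,
        provenance={k: "native" for k in
                    ("r_work", "r_free", "rms_bond", "rms_angle",
                     "clashscore", "rmsd_AB")},
    )
    return metrics, refined, q_hat


@dataclass
class BatchResult:
    ranked: List[ScoreBreakdown]
    metrics: Dict[str, ModelMetrics]
    refined: Dict[str, StructureModel]
    occupancies: Dict[str, float]
    weights: ResidueWeightSet
    manifest: RunManifest


def run_batch_models(
    reference: StructureModel,
    frames: Sequence[Tuple[str, StructureModel]],
    map_ref: DensityGrid,
    map_trig: DensityGrid,
    selection: ResidueSelection,
    config: Optional[PipelineConfig] = None,
    grid_spec: Optional[GridSpec] = None,
) -> BatchResult:
    """Run the full workflow over in-memory frames and rank them.

    ``frames`` is an ordered list of (frame_id, model); ``skip_frames``
    leading entries are excluded.  Frames that fail any stage are recorded as
    ``failed:<stage>`` in the manifest and left out of the ranking.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    kept = select_frames([fid for fid, _ in frames], config.skip_frames)
    frame_map = dict(frames)
    for fid, _ in frames:
        if fid not in kept:
            manifest.statuses[fid] = "skipped"

    if grid_spec is None:
        grid_spec = GridSpec(
            cell=map_trig.cell,
            spacing=tuple(map_trig.spacing),
            origin=tuple(map_trig.origin),
        )
    sel_keys = [k for k in reference.residues if k in selection]
    rest = StructureModel(
        residues={k: v for k, v in reference.residues.items() if k not in selection},
        unit_cell=reference.unit_cell, space_group=reference.space_group,
    )
    sel_model = StructureModel(
        residues={k: reference.residues[k] for k in sel_keys},
        unit_cell=reference.unit_cell, space_group=reference.space_group,
    )
    rho_rest = compute_model_density(rest, grid_spec)
    rho_a_sel = compute_model_density(sel_model, grid_spec)

    rng = np.random.default_rng(config.seed)
    free_mask = rng.random(int(np.prod(map_trig.shape))) < 0.05

    diff_iso = difference_grid(map_trig, map_ref)
    sigma_iso = estimate_sigma(diff_iso, config.sigma_method)
    weights = residue_difference_weights(
        diff_iso, reference, selection, sigma_iso,
        z_threshold=config.z_threshold, capture_radius=config.capture_radius,
    )

    def work(fid: str):
        return _measure_frame(
            fid, frame_map[fid], reference, selection, map_trig, grid_spec,
            rho_rest, rho_a_sel, free_mask, config,
        )

    results: Dict[str, Tuple[ModelMetrics, StructureModel, float]] = {}
    failures: Dict[str, str] = {}
    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            futures = {fid: pool.submit(work, fid) for fid in kept}
            for fid, fut in futures.items():
                try:
                    results[fid] = fut.result()
                except Exception as exc:  # per-frame failure policy: skip & log
                    failures[fid] = f"failed:{type(exc).__name__}: {exc}"
    else:
        for fid in kept:
            try:
                results[fid] = work(fid)
            except Exception as exc:
                failures[fid] = f"failed:{type(exc).__name__}: {exc}"

    for fid, status in failures.items():
        logger.warning("frame %s %s", fid, status)
        manifest.statuses[fid] = status
    if not results:
        raise RuntimeError(
            "all frames failed; first error: "
            + next(iter(failures.values()), "none")
        )
    ordered_ids = [fid for fid in kept if fid in results]
    batch = [results[fid][0] for fid in ordered_ids]

    if config.refine_log or config.molprobity_table or config.edstats_table:
        ingest_external_metrics(
            {m.model_id: m for m in batch},
            refine_log=config.refine_log or None,
            molprobity_table=config.molprobity_table or None,
            edstats_table=config.edstats_table or None,
            prefer=config.prefer or None,
        )

    breakdowns = composite_score(batch, weights)
    ranked = rank_models(breakdowns, batch)
    for fid in ordered_ids:
        manifest.statuses[fid] = "scored"
        manifest.provenance[fid] = dict(results[fid][0].provenance)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    return BatchResult(
        ranked=ranked,
        metrics={m.model_id: m for m in batch},
        refined={fid: results[fid][1] for fid in ordered_ids},
        occupancies={fid: results[fid][2] for fid in ordered_ids},
        weights=weights,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# File-based batch run
# ---------------------------------------------------------------------------

def _scores_frame(result: BatchResult) -> pd.DataFrame:
    rows = []
    for b in result.ranked:
        m = result.metrics[b.model_id]
        rows.append({
            "rank": b.rank,
            "model_id": b.model_id,
            "composite": round(b.composite, 6),
            "r_factor_term": round(b.r_factor_term, 6),
            "geometry_score": round(b.geometry_score, 6),
            "density_score": round(b.density_score, 6),
            "weighted_rszd": round(b.weighted_rszd, 6),
            "rscc_bar": round(b.rscc_bar, 6) if b.rscc_bar is not None else "",
            "rszo_bar": round(b.rszo_bar, 6) if b.rszo_bar is not None else "",
            "r_work": m.r_work,
            "r_free": m.r_free,
            "clashscore": m.clashscore,
            "rmsd_AB": m.rmsd_AB,
            "q_hat": result.occupancies.get(b.model_id, ""),
            "flags": ";".join(b.flags),
        })
    return pd.DataFrame(rows)


def run_batch(config: PipelineConfig) -> BatchResult:
    """File-based front end: read inputs, run the batch, write outputs.

    Outputs under ``config.output_dir``: refined models (PDB), scores.tsv,
    weights.tsv, manifest.json.  With ``resume``, frames whose refined model
    already exists are still re-measured (measurement is cheap and
    deterministic); the ranking is identical across re-runs.
    """
    config.validate_paths()
    reference = read_structure(config.reference)
    paths = sorted(globmod.glob(config.frames))
    if not paths:
        raise FileNotFoundError(f"no frames match {config.frames!r}")
    frames: List[Tuple[str, StructureModel]] = []
    parse_failures: Dict[str, str] = {}
    for p in paths:
        fid = Path(p).stem
        try:
            frames.append((fid, read_structure(p)))
        except Exception as exc:
            parse_failures[fid] = f"failed:parse: {exc}"
    map_trig = read_ccp4(config.map_trig)
    map_ref = read_ccp4(config.map_ref)
    selection = ResidueSelection.from_string(config.selection)
    # resolve selection sites against the reference (names come from it)
    keys = [k for k in reference.residues if k in selection]
    if len(keys) != len(selection):
        raise ValidationError("selection has sites missing from the reference")

    result = run_batch_models(
        reference, frames, map_ref, map_trig, selection, config
    )
    result.manifest.statuses.update(parse_failures)

    out = Path(config.output_dir)
    (out / "refined").mkdir(parents=True, exist_ok=True)
    for fid, model in result.refined.items():
        target = out / "refined" / f"{fid}.pdb"
        if not (config.resume and target.exists()):
            write_structure(model, target)
    scores = _scores_frame(result)
    with open(out / "scores.tsv", "w") as fh:
        fh.write(f"# trxscore {__version__} seed={config.seed}\n")
        scores.to_csv(fh, sep="\t", index=False)
    with open(out / "weights.tsv", "w") as fh:
        fh.write("residue\trho_pos\trho_neg\n")
        for key in result.weights.keys():
            fh.write(f"{key}\t{result.weights.rho_pos[key]:.6g}"
                     f"\t{result.weights.rho_neg[key]:.6g}\n")
    (out / "manifest.json").write_text(result.manifest.to_json())
    return result
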