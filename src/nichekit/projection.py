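"""Final models, multi-scenario transfers, and independent-data evaluation.

Each selected parameterization is refit on the complete occurrence set with
bootstrap replicates (default 10) and projected onto the calibration area
and every transfer scenario under the requested extrapolation modes.
Replicates are consolidated by the cell-wise median; when several
parameterizations are selected an additional cross-model "consensus" median
grid is produced.  Final models are then evaluated with the independent
occurrence set (partial ROC + omission), when one exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CandidateSpec
from .engine import GibbsModel, fit_replicates, predict
from .evaluation import (
    DEFAULT_BOOT_FRACTION,
    DEFAULT_E,
    DEFAULT_ITERATIONS,
    OmissionResult,
    ProcResult,
    omission_rate,
    partial_roc,
)
from .features import FeatureSpec
from .grids import EnvStack, Grid, ProjectLayout, extract_values, write_grid

__all__ = [
    "FinalModelRun",
    "FinalEvaluation",
    "consolidate",
    "build_final_models",
    "evaluate_final",
]


@dataclass
class FinalModelRun:
    spec: CandidateSpec
    replicates: list[GibbsModel]
    outputs: tuple[str, ...]
    modes: tuple[str, ...]
    calibration_grids: dict  # output -> Grid (median over replicates)
    scenario_grids: dict  # scenario -> mode -> output -> Grid


@dataclass
class FinalEvaluation:
    candidate_id: str
    proc: ProcResult | None
    omission: OmissionResult | None
    status: str = "ok"


def consolidate(grids: list[Grid]) -> Grid:
    """Cell-wise median of aligned grids; even counts average the middle two.

    A cell masked in any replicate is masked in the result.
    """
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError("misaligned replicate grids")
    mask = np.zeros(ref.shape, dtype=bool)
    for g in grids:
        mask |= g.nodata_mask
    stackvals = np.stack([g.values for g in grids])
    med = np.median(stackvals, axis=0)
    med = np.where(mask, 0.0, med)
    return ref.copy_with(med, mask)


def build_final_models(
    layout: ProjectLayout,
    specs: list[CandidateSpec],
    *,
    n_reps: int = 10,
    outputs: tuple[str, ...] = ("logistic",),
    modes: tuple[str, ...] = ("free", "clamp", "none"),
    threshold_knots: int = 25,
    hinge_knots: int = 25,
    background_size: int = 10_000,
    seed: int = 0,
    write_outputs: bool = True,
    stacks: dict | None = None,
) -> list[FinalModelRun]:
    """Refit each selected parameterization and project all scenarios.

    Grids are written under ``Final_Models/<candidate_id>/`` as
    ``<scenario>_<mode>_<output>.asc`` (calibration area as
    ``calibration_<output>.asc``); with more than one spec a cross-model
    consensus median is written under ``Final_Models/consensus/``.
    """
    occ_joint = layout.load_occurrences("joint")
    if stacks is None:
        stacks = {}
    runs: list[FinalModelRun] = []
    out_root = Path(layout.root) / "Final_Models"
    for si, spec in enumerate(specs):
        if spec.set_id not in stacks:
            stacks[spec.set_id] = layout.load_m_stack(spec.set_id)
        stack = stacks[spec.set_id]
        fspec = FeatureSpec.from_label(
            spec.fc, threshold_knots=threshold_knots, hinge_knots=hinge_knots
        )
        reps = fit_replicates(
            occ_joint,
            stack,
            spec.rm,
            fspec,
            n_reps,
            seed=(seed + 104729 * si) % (2**31),
            background_size=background_size,
        )
        calibration_grids = {
            out: consolidate([predict(m, stack, out, "free") for m in reps])
            for out in outputs
        }
        scenario_grids: dict = {}
        for scen in layout.scenarios(spec.set_id):
            g_stack = layout.load_g_stack(spec.set_id, scen)
            missing = [n for n in stack.names if n not in g_stack.names]
            if missing:
                raise ValueError(
                    f"scenario {scen!r} is missing layer(s) {missing}"
                )
            scenario_grids[scen] = {
                mode: {
                    out: consolidate([predict(m, g_stack, out, mode) for m in reps])
                    for out in outputs
                }
                for mode in modes
            }
        run = FinalModelRun(
            spec=spec,
            replicates=reps,
            outputs=tuple(outputs),
            modes=tuple(modes),
            calibration_grids=calibration_grids,
            scenario_grids=scenario_grids,
        )
        runs.append(run)
        if write_outputs:
            cdir = out_root / spec.candidate_id
            cdir.mkdir(parents=True, exist_ok=True)
            for out, grid in calibration_grids.items():
                write_grid(grid, cdir / f"calibration_{out}.asc")
            for scen, per_mode in scenario_grids.items():
                for mode, per_out in per_mode.items():
                    for out, grid in per_out.items():
                        write_grid(grid, cdir / f"{scen}_{mode}_{out}.asc")
    if write_outputs and len(runs) > 1:
        cdir = out_root / "consensus"
        cdir.mkdir(parents=True, exist_ok=True)
        for out in outputs:
            grids = [r.calibration_grids[out] for r in runs]
            if all(grids[0].same_geometry(g) for g in grids):
                write_grid(consolidate(grids), cdir / f"calibration_{out}.asc")
            else:
                warnings.warn(
                    "consensus skipped: selected models span differently "
                    "shaped predictor sets",
                    stacklevel=2,
                )
                break
    return runs


def evaluate_final(
    runs: list[FinalModelRun],
    layout: ProjectLayout,
    *,
    E: float = DEFAULT_E,
    iterations: int = DEFAULT_ITERATIONS,
    boot_fraction: float = DEFAULT_BOOT_FRACTION,
    seed: int = 0,
    output: str = "logistic",
    write_outputs: bool = True,
    include_consensus: bool = True,
) -> list[FinalEvaluation]:
    """Evaluate final models with the independent occurrence set.

    Statistics are computed on the consolidated calibration-area prediction;
    the omission threshold derives from the complete occurrence set's
    suitabilities.  With no independent data the evaluation is skipped with
    an explicit status rather than raised.
    """
    if not layout.independent_csv.exists():
        return [
            FinalEvaluation(r.spec.candidate_id, None, None, "skipped: no independent data")
            for r in runs
        ]
    occ_ind = layout.load_occurrences("independent")
    occ_joint = layout.load_occurrences("joint")
    evals: list[FinalEvaluation] = []
    jobs: list[tuple[str, Grid]] = []
    for run in runs:
        if output not in run.calibration_grids:
            evals.append(
                FinalEvaluation(
                    run.spec.candidate_id, None, None, f"skipped: no {output} output"
                )
            )
            continue
        jobs.append((run.spec.candidate_id, run.calibration_grids[output]))
    if include_consensus and len(jobs) > 1:
        grids = [g for _, g in jobs]
        if all(grids[0].same_geometry(g) for g in grids):
            jobs.append(("consensus", consolidate(grids)))
    for i, (cid, grid) in enumerate(jobs):
        ind_vals = extract_values(grid, occ_ind)
        joint_vals = extract_values(grid, occ_joint)
        proc = partial_roc(
            grid,
            ind_vals,
            E=E,
            iterations=iterations,
            boot_fraction=boot_fraction,
            seed=(seed + 15485863 * i) % (2**31),
        )
        om = omission_rate(joint_vals, ind_vals, E=E)
        evals.append(FinalEvaluation(cid, proc, om))
    if write_outputs:
        rows = []
        for ev in evals:
            rows.append(
                {
                    "candidate_id": ev.candidate_id,
                    "mean_auc_ratio": ev.proc.mean_auc_ratio if ev.proc else np.nan,
                    "p_value": ev.proc.p_value if ev.proc else np.nan,
                    "omission_rate": ev.omission.omission_rate if ev.omission else np.nan,
                    "status": ev.status,
                }
            )
        pd.DataFrame(rows).to_csv(Path(layout.root) / "final_evaluation.csv", index=False)
    return evals
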