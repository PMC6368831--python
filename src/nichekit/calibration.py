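"""Candidate-model calibration grid.

Candidates are the Cartesian product of regularization multipliers, feature
class combinations, and predictor sets.  For every candidate two models are
fitted: one on the complete ("joint") occurrence set, used later for the
AICc complexity statistic, and one on the training subset, used for the
significance and omission statistics against the held-out test records.
Results are written to disk candidate-by-candidate so failed fits never
abort the batch.
"""

from __future__ import annotations

import csv
import itertools
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import GibbsModel, fit_stack, predict
from .features import FEATURE_CLASSES, FeatureSpec
from .grids import EnvStack, ProjectLayout, write_grid

__all__ = [
    "DEFAULT_RM_GRID",
    "DEFAULT29",
    "ALL31",
    "FC_CATALOGS",
    "CandidateSpec",
    "CandidatePair",
    "default_rm_grid",
    "fc_catalog",
    "enumerate_candidates",
    "run_calibration",
]

# 0.1-1.0 by 0.1, 2-6 by 1, then 8 and 10: the 17-value default grid.
DEFAULT_RM_GRID: tuple[float, ...] = tuple(
    [round(0.1 * i, 1) for i in range(1, 11)] + [2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0]
)


def _all_nonempty_subsets() -> list[str]:
    subsets = []
    for r in range(1, 6):
        for combo in itertools.combinations(FEATURE_CLASSES, r):
            subsets.append("".join(combo))
    return subsets


ALL31: tuple[str, ...] = tuple(_all_nonempty_subsets())
# The 29-combination default catalog: all nonempty subsets of {l,q,p,t,h}
# except the two degenerate single-class sets {p} and {t} (a product-only or
# threshold-only model has no useful univariate response shape).
DEFAULT29: tuple[str, ...] = tuple(s for s in ALL31 if s not in ("p", "t"))

FC_CATALOGS = {"default29": DEFAULT29, "all31": ALL31}


def default_rm_grid() -> tuple[float, ...]:
    """The 17-value regularization-multiplier grid."""
    return DEFAULT_RM_GRID


def fc_catalog(name: str = "default29") -> tuple[str, ...]:
    try:
        return FC_CATALOGS[name]
    except KeyError:
        raise ValueError(
            f"unknown feature-class catalog {name!r}; available: {sorted(FC_CATALOGS)}"
        ) from None


def _format_rm(rm: float) -> str:
    return f"{rm:g}"


@dataclass(frozen=True)
class CandidateSpec:
    """One point of the calibration grid."""

    rm: float
    fc: str
    set_id: str

    def __post_init__(self) -> None:
        if self.rm <= 0:
            raise ValueError("rm must be positive")
        FeatureSpec.from_label(self.fc)  # validates classes

    @property
    def candidate_id(self) -> str:
        return f"M_{_format_rm(self.rm)}_F_{self.fc}_{self.set_id}"


@dataclass
class CandidatePair:
    """Fitted models for one candidate: full-occurrence and training-only."""

    spec: CandidateSpec
    model_full: GibbsModel
    model_train: GibbsModel


def _validate_grid(rm_grid, fc_labels) -> None:
    rms = list(rm_grid)
    if not rms or any(r <= 0 for r in rms):
        raise ValueError("rm grid must be nonempty and positive")
    if any(b <= a for a, b in zip(rms, rms[1:])):
        raise ValueError("rm grid must be strictly increasing")
    labels = list(fc_labels)
    if not labels:
        raise ValueError("feature-class catalog must be nonempty")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate feature-class combinations")


def enumerate_candidates(
    rm_grid=DEFAULT_RM_GRID,
    fc_labels=DEFAULT29,
    set_ids=("Set_1",),
) -> list[CandidateSpec]:
    """Cartesian product of the grid in (set, rm, fc) lexicographic order."""
    _validate_grid(rm_grid, fc_labels)
    set_ids = list(set_ids)
    if not set_ids:
        raise ValueError("need at least one predictor set")
    if len(set(set_ids)) != len(set_ids):
        raise ValueError("duplicate set ids")
    specs = [
        CandidateSpec(rm=float(rm), fc=fc, set_id=s)
        for s in set_ids
        for rm in rm_grid
        for fc in fc_labels
    ]
    if len({c.candidate_id for c in specs}) != len(specs):
        raise ValueError("candidate ids collide (rm values equal at printed precision)")
    return specs


def run_calibration(
    layout: ProjectLayout,
    rm_grid=DEFAULT_RM_GRID,
    fc_labels=DEFAULT29,
    set_ids=None,
    *,
    threshold_knots: int = 25,
    hinge_knots: int = 25,
    background_size: int = 10_000,
    seed: int = 0,
    write_predictions: bool = True,
    stacks: dict[str, EnvStack] | None = None,
) -> tuple[list[CandidatePair], list[dict]]:
    """Fit the full candidate grid against a project layout.

    Each candidate's two models are written under
    ``<root>/Candidate_models/<candidate_id>/`` (model JSON, optional
    calibration-area raw/logistic grids); a batch log CSV records per-
    candidate status.  Per-candidate failures are logged, not raised.
    """
    problems = layout.validate()
    if problems:
        raise ValueError("invalid project layout: " + "; ".join(problems))
    if set_ids is None:
        set_ids = layout.set_ids()
    specs = enumerate_candidates(rm_grid, fc_labels, set_ids)
    occ_joint = layout.load_occurrences("joint")
    occ_train = layout.load_occurrences("train")
    if stacks is None:
        stacks = {}
    out_dir = layout.root / "Candidate_models"
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs: list[CandidatePair] = []
    log: list[dict] = []
    for i, spec in enumerate(specs):
        t0 = time.time()
        try:
            if spec.set_id not in stacks:
                stacks[spec.set_id] = layout.load_m_stack(spec.set_id)
            stack = stacks[spec.set_id]
            fspec = FeatureSpec.from_label(
                spec.fc, threshold_knots=threshold_knots, hinge_knots=hinge_knots
            )
            # derive per-candidate seeds from the run seed: deterministic,
            # independent of batch order
            cand_seed = (seed + 1009 * i) % (2**31)
            model_full = fit_stack(
                occ_joint, stack, spec.rm, fspec,
                background_size=background_size, seed=cand_seed,
            )
            model_train = fit_stack(
                occ_train, stack, spec.rm, fspec,
                background_size=background_size, seed=cand_seed,
            )
            pair = CandidatePair(spec, model_full, model_train)
            cdir = out_dir / spec.candidate_id
            cdir.mkdir(parents=True, exist_ok=True)
            model_full.save(cdir / "model_full.json")
            model_train.save(cdir / "model_train.json")
            if write_predictions:
                write_grid(predict(model_full, stack, "raw"), cdir / "calibration_raw.asc")
                write_grid(
                    predict(model_train, stack, "logistic"),
                    cdir / "calibration_train_logistic.asc",
                )
            pairs.append(pair)
            log.append(
                {
                    "candidate_id": spec.candidate_id,
                    "status": "ok",
                    "message": "",
                    "seconds": round(time.time() - t0, 3),
                }
            )
        except Exception as exc:
            log.append(
                {
                    "candidate_id": spec.candidate_id,
                    "status": "failed",
                    "message": str(exc),
                    "seconds": round(time.time() - t0, 3),
                }
            )
    with open(out_dir / "calibration_log.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["candidate_id", "status", "message", "seconds"]
        )
        writer.writeheader()
        writer.writerows(log)
    return pairs, log
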