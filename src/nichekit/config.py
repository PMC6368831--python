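"""Run configuration: YAML round-trip, validation, per-stage seeds.

Every random procedure in the toolkit draws from a seed derived from the
single run seed with a fixed per-stage offset, so two runs with the same
configuration are identical in every CSV output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calibration import DEFAULT_RM_GRID, FC_CATALOGS

# per-stage seed offsets (documented contract)
STAGE_OFFSETS = {
    "simulate": 0,
    "calibrate": 1,
    "evaluate": 2,
    "final": 3,
    "feval": 4,
    "mop": 5,
}


@dataclass
class RunConfig:
    root: str = "."
    rm_grid: list = field(default_factory=lambda: list(DEFAULT_RM_GRID))
    fc_catalog: str = "default29"
    fc_subset: list = field(default_factory=list)  # optional explicit combos
    E: float = 5.0
    alpha: float = 0.05
    delta_max: float = 2.0
    proc_iterations: int = 500
    proc_boot_fraction: float = 0.5
    n_reps: int = 10
    outputs: list = field(default_factory=lambda: ["logistic"])
    modes: list = field(default_factory=lambda: ["free", "clamp", "none"])
    mop_percents: list = field(default_factory=lambda: [5.0])
    threshold_knots: int = 25
    hinge_knots: int = 25
    background_size: int = 10000
    seed: int = 0
    workers: int = 1

    def validate(self) -> None:
        from .engine import EXTRAPOLATION_MODES

        errors = []
        rms = [float(r) for r in self.rm_grid]
        if not rms or any(r <= 0 for r in rms):
            errors.append("rm_grid must be nonempty and positive")
        elif any(b <= a for a, b in zip(rms, rms[1:])):
            errors.append("rm_grid must be strictly increasing")
        if self.fc_catalog not in FC_CATALOGS:
            errors.append(f"fc_catalog must be one of {sorted(FC_CATALOGS)}")
        if not (0 <= self.E < 100):
            errors.append("E must be in [0, 100)")
        if not (0 < self.alpha < 1):
            errors.append("alpha must be in (0, 1)")
        if self.delta_max < 0:
            errors.append("delta_max must be >= 0")
        if self.proc_iterations < 1:
            errors.append("proc_iterations must be >= 1")
        if not (0 < self.proc_boot_fraction <= 1):
            errors.append("proc_boot_fraction must be in (0, 1]")
        if self.n_reps < 1:
            errors.append("n_reps must be >= 1")
        bad_out = set(self.outputs) - {"raw", "logistic", "cloglog"}
        if bad_out:
            errors.append(f"unknown outputs: {sorted(bad_out)}")
        bad_modes = set(self.modes) - set(EXTRAPOLATION_MODES)
        if bad_modes:
            errors.append(f"unknown modes: {sorted(bad_modes)}")
        if any(not (0 < p <= 100) for p in self.mop_percents):
            errors.append("mop_percents must lie in (0, 100]")
        if self.threshold_knots < 1 or self.hinge_knots < 1:
            errors.append("knot counts must be >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def fc_labels(self) -> list[str]:
        if self.fc_subset:
            return list(self.fc_subset)
        return list(FC_CATALOGS[self.fc_catalog])

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + STAGE_OFFSETS[stage] * 1_000_003) % (2**31)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
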