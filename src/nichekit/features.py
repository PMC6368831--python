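"""Maxent feature expansion: linear, quadratic, product, threshold, hinge.

Variables are first rescaled to [0, 1] by their calibration (min, max); all
feature classes operate on the rescaled values.  Threshold and hinge knots
are placed evenly on the rescaled (0, 1) interval, independent of the
presence sample, so the design is deterministic given the calibration ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

FEATURE_CLASSES = ("l", "q", "p", "t", "h")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand, and how many knots to use.

    ``threshold_knots`` counts step-function knots per variable;
    ``hinge_knots`` counts knots per variable *per direction* (forward and
    reverse hinges each get their own set).
    """

    classes: tuple[str, ...]
    threshold_knots: int = 25
    hinge_knots: int = 25

    def __post_init__(self) -> None:
        cls = tuple(sorted(set(self.classes), key=FEATURE_CLASSES.index))
        object.__setattr__(self, "classes", cls)
        if not cls:
            raise ValueError("feature classes must be nonempty")
        unknown = set(cls) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.threshold_knots < 1 or self.hinge_knots < 1:
            raise ValueError("knot counts must be >= 1")

    @property
    def label(self) -> str:
        return "".join(self.classes)

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "FeatureSpec":
        return cls(classes=tuple(label), **kwargs)


@dataclass
class FeatureDef:
    """Provenance of one design-matrix column."""

    kind: str  # "linear" | "quadratic" | "product" | "threshold" | "hinge_fwd" | "hinge_rev"
    variables: tuple[int, ...]  # source variable indices
    knot: float | None = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "variables": list(self.variables), "knot": self.knot}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDef":
        return cls(kind=d["kind"], variables=tuple(d["variables"]), knot=d["knot"])

    @property
    def penalty_class(self) -> str:
        return {
            "linear": "lq",
            "quadratic": "lq",
            "product": "p",
            "threshold": "t",
            "hinge_fwd": "h",
            "hinge_rev": "h",
        }[self.kind]


def rescale(values: np.ndarray, ranges) -> np.ndarray:
    """Map raw variable values onto [0, 1] by the calibration ranges.

    Values outside the range map outside [0, 1]; clamping, where requested,
    happens before this call.
    """
    values = np.asarray(values, dtype=float)
    lo = np.array([r[0] for r in ranges], dtype=float)
    hi = np.array([r[1] for r in ranges], dtype=float)
    span = hi - lo
    if np.any(span <= 0):
        bad = int(np.flatnonzero(span <= 0)[0])
        raise ValueError(f"constant variable at index {bad} (min == max)")
    return (values - lo) / span


def feature_definitions(n_vars: int, spec: FeatureSpec) -> list[FeatureDef]:
    """Enumerate design columns for ``n_vars`` variables under ``spec``."""
    defs: list[FeatureDef] = []
    if "l" in spec.classes:
        defs += [FeatureDef("linear", (v,)) for v in range(n_vars)]
    if "q" in spec.classes:
        defs += [FeatureDef("quadratic", (v,)) for v in range(n_vars)]
    if "p" in spec.classes:
        defs += [FeatureDef("product", (i, j)) for i, j in combinations(range(n_vars), 2)]
    if "t" in spec.classes:
        knots = np.linspace(0, 1, spec.threshold_knots + 2)[1:-1]
        defs += [
            FeatureDef("threshold", (v,), float(k))
            for v in range(n_vars)
            for k in knots
        ]
    if "h" in spec.classes:
        knots = np.linspace(0, 1, spec.hinge_knots + 2)[1:-1]
        for v in range(n_vars):
            defs += [FeatureDef("hinge_fwd", (v,), float(k)) for k in knots]
            defs += [FeatureDef("hinge_rev", (v,), float(k)) for k in knots]
    return defs


def evaluate_features(z: np.ndarray, defs: list[FeatureDef]) -> np.ndarray:
    """Design matrix for rescaled values ``z`` (n_rows, n_vars)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    cols = np.empty((z.shape[0], len(defs)), dtype=float)
    for j, fd in enumerate(defs):
        if fd.kind == "linear":
            cols[:, j] = z[:, fd.variables[0]]
        elif fd.kind == "quadratic":
            cols[:, j] = z[:, fd.variables[0]] ** 2
        elif fd.kind == "product":
            cols[:, j] = z[:, fd.variables[0]] * z[:, fd.variables[1]]
        elif fd.kind == "threshold":
            cols[:, j] = (z[:, fd.variables[0]] > fd.knot).astype(float)
        elif fd.kind == "hinge_fwd":
            k = fd.knot
            cols[:, j] = np.maximum(0.0, (z[:, fd.variables[0]] - k) / (1.0 - k))
        elif fd.kind == "hinge_rev":
            k = fd.knot
            cols[:, j] = np.maximum(0.0, (k - z[:, fd.variables[0]]) / k)
        else:  # pragma: no cover
            raise ValueError(f"unknown feature kind {fd.kind!r}")
    return cols


def build_features(
    stack_values: np.ndarray, spec: FeatureSpec, ranges
) -> tuple[np.ndarray, list[FeatureDef]]:
    """Rescale by calibration ranges and expand into the design matrix."""
    z = rescale(stack_values, ranges)
    defs = feature_definitions(z.shape[1], spec)
    return evaluate_features(z, defs), defs
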