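"""Built-in Maxent-style model engine.

The model is a Gibbs density over the calibration cells,

    P(cell c) = exp(lambda . f(c)) / Z,     Z = sum_c exp(lambda . f(c)),

with features f expanded from the environmental variables (see
:mod:`nichekit.features`) and coefficients ``lambda`` chosen to minimize the
L1-penalized mean negative log-likelihood of the presence cells

    log Z - mean_i lambda . f(x_i)  +  sum_j beta_j |lambda_j|,

where ``beta_j = rm * base(class_j, n_presences) * s_j`` scales with the
regularization multiplier ``rm``, a feature-class- and sample-size-dependent
base value interpolated from Maxent's published default table, and the
feature's standard deviation ``s_j`` over the presence sample.  The convex
problem is solved by proximal gradient descent (FISTA) with soft
thresholding, which yields exact zeros so the number of model parameters is
well defined.

This is a re-derivation in the spirit of maxnet, not a wrapper of
Maxent.jar; structural equivalence (feature families, penalty structure,
raw/logistic/cloglog outputs, clamping) is provided, bitwise equality with
the Java program is not claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .features import (
    FeatureDef,
    FeatureSpec,
    build_features,
    evaluate_features,
    feature_definitions,
    rescale,
)
from .grids import EnvStack, Grid, OccurrenceSet, occurrence_cells

__all__ = [
    "GibbsModel",
    "ConvergenceError",
    "EXTRAPOLATION_MODES",
    "fit",
    "fit_stack",
    "fit_replicates",
    "predict",
    "predict_values",
    "count_parameters",
]

EXTRAPOLATION_MODES = ("free", "clamp", "none")

# Maxent's default base regularization, keyed by feature class and tabulated
# on the number of presences; linear interpolation, constant outside range.
BASE_REGULARIZATION = {
    "lq": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "p": ([0, 10, 17], [2.6, 1.6, 1.4]),
    "t": ([0, 100], [2.0, 1.0]),
    "h": ([0, 1], [0.5, 0.5]),
}

DEFAULT_BACKGROUND_SIZE = 10_000
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def base_regularization(penalty_class: str, n_presences: int) -> float:
    ns, vals = BASE_REGULARIZATION[penalty_class]
    return float(np.interp(n_presences, ns, vals))


@dataclass
class GibbsModel:
    """Fitted Maxent-style model."""

    feature_defs: list[FeatureDef]
    coefficients: np.ndarray
    offset: float
    log_z: float
    entropy: float
    ranges: list[tuple[float, float]]
    var_names: list[str]
    rm: float
    n_presences: int
    spec: FeatureSpec
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_defs": [fd.to_dict() for fd in self.feature_defs],
            "coefficients": self.coefficients.tolist(),
            "offset": self.offset,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "ranges": [list(r) for r in self.ranges],
            "var_names": list(self.var_names),
            "rm": self.rm,
            "n_presences": self.n_presences,
            "spec": {
                "classes": list(self.spec.classes),
                "threshold_knots": self.spec.threshold_knots,
                "hinge_knots": self.spec.hinge_knots,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GibbsModel":
        return cls(
            feature_defs=[FeatureDef.from_dict(x) for x in d["feature_defs"]],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            offset=float(d["offset"]),
            log_z=float(d["log_z"]),
            entropy=float(d["entropy"]),
            ranges=[tuple(r) for r in d["ranges"]],
            var_names=list(d["var_names"]),
            rm=float(d["rm"]),
            n_presences=int(d["n_presences"]),
            spec=FeatureSpec(
                classes=tuple(d["spec"]["classes"]),
                threshold_knots=d["spec"]["threshold_knots"],
                hinge_knots=d["spec"]["hinge_knots"],
            ),
        )

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GibbsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def count_parameters(model: GibbsModel) -> int:
    """Number of features with nonzero coefficient (exact zeros from L1)."""
    return model.n_parameters


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _solve_l1_gibbs(
    B: np.ndarray,
    f_bar: np.ndarray,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, dict]:
    """Minimize logsumexp(B @ lam) - f_bar . lam + beta . |lam| by FISTA.

    B is the background design matrix (cells x features); f_bar the mean
    presence feature vector.  Backtracking line search on the local Lipschitz
    constant; adaptive restart of the momentum sequence.
    """
    n_feat = B.shape[1]
    lam = np.zeros(n_feat)
    y = lam.copy()
    t_mom = 1.0
    L = 1.0

    def smooth(v):
        eta = B @ v
        m = logsumexp(eta)
        p = np.exp(eta - m)
        return m - f_bar @ v, B.T @ p - f_bar

    g_y, grad_y = smooth(y)
    obj_prev = np.inf
    for it in range(max_iter):
        # backtracking
        while True:
            cand = _soft_threshold(y - grad_y / L, beta / L)
            diff = cand - y
            g_cand, grad_cand = smooth(cand)
            if g_cand <= g_y + grad_y @ diff + 0.5 * L * (diff @ diff) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:  # pathological; accept the step anyway
                break
        step = cand - lam
        max_step = float(np.max(np.abs(step))) if step.size else 0.0
        obj = g_cand + beta @ np.abs(cand)
        # adaptive restart when momentum overshoots
        if obj > obj_prev:
            t_new = 1.0
            y_new = cand
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            y_new = cand + ((t_mom - 1.0) / t_new) * step
        lam, y, t_mom = cand, y_new, t_new
        if np.array_equal(y, cand):
            g_y, grad_y = g_cand, grad_cand
        else:
            g_y, grad_y = smooth(y)
        L = max(L * 0.9, 1e-6)
        if max_step < tol or abs(obj_prev - obj) <= 1e-13 * max(1.0, abs(obj)):
            return lam, {"iterations": it + 1, "objective": float(obj), "converged": True}
        obj_prev = obj
    raise ConvergenceError(
        f"solver did not converge in {max_iter} iterations "
        f"(last step {max_step:.3g}, tol {tol:.3g})",
        {"iterations": max_iter, "objective": float(obj), "last_step": max_step},
    )


def _penalty_weights(
    P: np.ndarray, B: np.ndarray, defs: list[FeatureDef], rm: float, n_presences: int
) -> np.ndarray:
    s = P.std(axis=0)
    s_bg = B.std(axis=0)
    s = np.where(s < 1e-6, s_bg, s)  # constant over presences: use background spread
    s = np.maximum(s, 1e-3)  # never leave a feature unpenalized
    base = np.array([base_regularization(fd.penalty_class, n_presences) for fd in defs])
    return rm * base * s


def fit(
    presences: np.ndarray,
    background: np.ndarray,
    rm: float,
    spec: FeatureSpec,
    *,
    defs: list[FeatureDef] | None = None,
    ranges=None,
    var_names: list[str] | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> GibbsModel:
    """Fit the penalized Gibbs model.

    ``presences`` and ``background`` are design rows when ``defs`` is given,
    otherwise raw variable matrices that are rescaled (by ``ranges`` or the
    background min/max) and expanded under ``spec``.
    """
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if defs is None:
        if ranges is None:
            ranges = [
                (float(background[:, j].min()), float(background[:, j].max()))
                for j in range(background.shape[1])
            ]
        zp = rescale(presences, ranges)
        zb = rescale(background, ranges)
        defs = feature_definitions(background.shape[1], spec)
        P = evaluate_features(zp, defs)
        B = evaluate_features(zb, defs)
    else:
        P, B = presences, background
        if ranges is None:
            ranges = []
    n_presences = P.shape[0]
    if n_presences < 2 or np.unique(P, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 unique presence cells")
    beta = _penalty_weights(P, B, defs, rm, n_presences)
    lam, diag = _solve_l1_gibbs(B, P.mean(axis=0), beta, tol, max_iter)
    eta = B @ lam
    log_z = float(logsumexp(eta))
    p = np.exp(eta - log_z)
    entropy = float(-np.sum(p * np.log(np.clip(p, 1e-300, None))))
    assert abs(p.sum() - 1.0) < 1e-8
    if var_names is None:
        n_vars = max((max(fd.variables) for fd in defs), default=-1) + 1
        var_names = [f"var_{i}" for i in range(n_vars)]
    return GibbsModel(
        feature_defs=defs,
        coefficients=lam,
        offset=0.0,
        log_z=log_z,
        entropy=entropy,
        ranges=[tuple(r) for r in ranges],
        var_names=list(var_names),
        rm=float(rm),
        n_presences=n_presences,
        spec=spec,
        diagnostics=diag,
    )


def _background_matrix(
    stack: EnvStack, background_size: int, rng: np.random.Generator
) -> np.ndarray:
    V = stack.values_matrix()
    if background_size and V.shape[0] > background_size:
        idx = rng.choice(V.shape[0], size=background_size, replace=False)
        V = V[idx]
    return V


def fit_stack(
    occ: OccurrenceSet,
    stack: EnvStack,
    rm: float,
    spec: FeatureSpec,
    *,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    presence_cells: np.ndarray | None = None,
) -> GibbsModel:
    """Fit from an occurrence set and environmental stack.

    Presences are deduplicated to one per cell; background is every unmasked
    calibration cell, or a seeded uniform sample when there are more than
    ``background_size``.  The normalization constant and entropy are then
    recomputed over *all* unmasked calibration cells so the raw output sums
    to 1 over the calibration area regardless of background sampling.
    """
    rng = np.random.default_rng(seed)
    ref = stack.layers[0]
    if presence_cells is None:
        presence_cells = occurrence_cells(stack, occ, dedupe=True)
    if presence_cells.size < 2:
        raise ValueError("need at least 2 unique presence cells on the grid")
    rows, cols = np.divmod(presence_cells, ref.shape[1])
    pres_vals = np.column_stack([g.values[rows, cols] for g in stack.layers])
    bg_vals = _background_matrix(stack, background_size, rng)
    model = fit(
        pres_vals,
        bg_vals,
        rm,
        spec,
        ranges=stack.ranges,
        var_names=stack.names,
        tol=tol,
        max_iter=max_iter,
    )
    # renormalize over the full calibration area
    z_all = rescale(stack.values_matrix(), model.ranges)
    F = evaluate_features(z_all, model.feature_defs)
    eta = F @ model.coefficients
    model.log_z = float(logsumexp(eta))
    p = np.exp(eta - model.log_z)
    model.entropy = float(-np.sum(p * np.log(np.clip(p, 1e-300, None))))
    return model


def fit_replicates(
    occ: OccurrenceSet,
    stack: EnvStack,
    rm: float,
    spec: FeatureSpec,
    n_reps: int,
    seed: int = 0,
    **fit_kwargs,
) -> list[GibbsModel]:
    """Bootstrap replicates: refit on with-replacement resamples of the
    occurrence records (size n), deterministic given the seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(occ)
    models = []
    for rep in range(n_reps):
        idx = rng.integers(0, n, size=n)
        boot = OccurrenceSet(occ.species, occ.records[idx], occ.role)
        try:
            models.append(
                fit_stack(boot, stack, rm, spec, seed=int(rng.integers(2**31)), **fit_kwargs)
            )
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} failed: {exc}") from exc
    return models


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _transform(raw: np.ndarray, entropy: float, output: str) -> np.ndarray:
    if output == "raw":
        return raw
    s = np.exp(entropy) * raw
    if output == "logistic":
        return s / (1.0 + s)
    if output == "cloglog":
        return 1.0 - np.exp(-s)
    raise ValueError(f"unknown output {output!r}")


def predict_values(
    model: GibbsModel,
    values: np.ndarray,
    output: str = "raw",
    mode: str = "free",
) -> np.ndarray:
    """Predict suitability for raw variable rows (columns = model.var_names)."""
    if mode not in EXTRAPOLATION_MODES:
        raise ValueError(f"mode must be one of {EXTRAPOLATION_MODES}")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    lo = np.array([r[0] for r in model.ranges])
    hi = np.array([r[1] for r in model.ranges])
    out_of_range = np.any((values < lo) | (values > hi), axis=1)
    if mode in ("clamp", "none"):
        values = np.clip(values, lo, hi)
    z = rescale(values, model.ranges)
    F = evaluate_features(z, model.feature_defs)
    raw = np.exp(F @ model.coefficients - model.log_z)
    if mode == "none":
        raw = np.where(out_of_range, 0.0, raw)
    return _transform(raw, model.entropy, output)


def predict(
    model: GibbsModel,
    env: EnvStack,
    output: str = "raw",
    mode: str = "free",
) -> Grid:
    """Project the model onto an environmental stack.

    ``free`` extrapolates feature trends beyond the calibration ranges;
    ``clamp`` clips each variable to its calibration range first; ``none``
    clamps and then zeroes every cell with any variable outside its range.
    """
    missing = [n for n in model.var_names if n not in env.names]
    if missing:
        raise ValueError(f"environmental stack missing variable(s): {missing}")
    order = [env.names.index(n) for n in model.var_names]
    X = env.full_matrix()[:, order]
    valid = ~env.mask.ravel()
    out = np.zeros(X.shape[0])
    out[valid] = predict_values(model, X[valid], output=output, mode=mode)
    return env.grid_like(out)
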