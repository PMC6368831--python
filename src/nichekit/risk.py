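"""Extrapolation-risk surfaces: mobility-oriented parity (MOP) and MESS.

MOP measures, for every cell of a transfer region G, the mean multivariate
environmental distance to the nearest p% of the calibration-region (M)
conditions, normalized into a similarity in [0, 1]; cells with any variable
outside its M range are *strict extrapolation* and fixed at 0.  MESS is the
classic percentile-based novelty surface (minimum over variables of a
per-variable similarity score), negative exactly where a variable leaves
its M range — so the MOP strict mask and MESS < 0 agree cell-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import EnvStack, Grid, ProjectLayout, write_grid

__all__ = ["MopResult", "MessResult", "mop", "mop_batch", "mess"]

# sentinel for MESS with a constant M variable and g outside it
NEG_SENTINEL = -1e30


@dataclass
class MopResult:
    similarity: Grid
    strict_mask: Grid  # 0/1 grid
    percent: float
    scenario: str = ""
    max_distance: float = float("nan")


@dataclass
class MessResult:
    mess: Grid
    most_dissimilar_variable: Grid  # layer index per cell


def _strict_flags(G: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.any((G < lo) | (G > hi), axis=1)


def mop(
    m_values: np.ndarray,
    g_stack: EnvStack,
    percent: float = 5.0,
    m_subsample: int = 10_000,
    seed: int = 0,
    standardize: bool = False,
    chunk: int = 2048,
) -> MopResult:
    """Mobility-oriented parity of a transfer stack against M conditions.

    ``m_values`` is the (cells x variables) matrix of calibration-region
    conditions, column order matching ``g_stack`` layers.  Distances are
    Euclidean on raw variable units unless ``standardize`` z-scores both
    sides by the M mean/sd.  Strictness uses the full M set's per-variable
    range even when distances use a subsample.
    """
    M_full = np.asarray(m_values, dtype=float)
    if M_full.size == 0:
        raise ValueError("empty calibration (M) matrix")
    if M_full.shape[1] != g_stack.n_layers:
        raise ValueError(
            f"variable mismatch: M has {M_full.shape[1]}, G has {g_stack.n_layers}"
        )
    if not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    lo, hi = M_full.min(axis=0), M_full.max(axis=0)
    rng = np.random.default_rng(seed)
    M = M_full
    if m_subsample and M.shape[0] > m_subsample:
        M = M[rng.choice(M.shape[0], size=m_subsample, replace=False)]
    Gmat = g_stack.values_matrix()
    strict = _strict_flags(Gmat, lo, hi)
    if standardize:
        mu, sd = M.mean(axis=0), M.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Ms, Gs = (M - mu) / sd, (Gmat - mu) / sd
    else:
        Ms, Gs = M, Gmat
    k = int(np.ceil(percent / 100.0 * Ms.shape[0]))
    dists = np.empty(Gs.shape[0])
    for start in range(0, Gs.shape[0], chunk):
        block = Gs[start : start + chunk]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            - 2.0 * block @ Ms.T
            + np.sum(Ms**2, axis=1)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        if k < Ms.shape[0]:
            part = np.partition(d2, k - 1, axis=1)[:, :k]
        else:
            part = d2
        dists[start : start + chunk] = np.sqrt(part).mean(axis=1)
    non_strict = ~strict
    if not non_strict.any():
        warnings.warn("all transfer cells are strict extrapolation", stacklevel=2)
        sim = np.zeros_like(dists)
        max_d = float("nan")
    else:
        max_d = float(dists[non_strict].max())
        sim = 1.0 - dists / max_d if max_d > 0 else np.ones_like(dists)
        sim = np.clip(sim, 0.0, 1.0)
        sim[strict] = 0.0
    valid = ~g_stack.mask.ravel()
    full_sim = np.zeros(g_stack.mask.size)
    full_sim[valid] = sim
    full_strict = np.zeros(g_stack.mask.size)
    full_strict[valid] = strict.astype(float)
    return MopResult(
        similarity=g_stack.grid_like(full_sim),
        strict_mask=g_stack.grid_like(full_strict),
        percent=float(percent),
        max_distance=max_d,
    )


def mop_batch(
    layout: ProjectLayout,
    percents=(5.0,),
    *,
    m_subsample: int = 10_000,
    seed: int = 0,
    standardize: bool = False,
    write_outputs: bool = True,
    stacks: dict | None = None,
) -> tuple[list[MopResult], list[dict]]:
    """MOP for every (predictor set, scenario, percent) in the project.

    Per-scenario failures are logged and the batch continues; results land
    under ``MOP_results/<set>/<scenario>/mop_<percent>.asc``.
    """
    if stacks is None:
        stacks = {}
    results: list[MopResult] = []
    log: list[dict] = []
    out_root = Path(layout.root) / "MOP_results"
    for set_id in layout.set_ids():
        try:
            if set_id not in stacks:
                stacks[set_id] = layout.load_m_stack(set_id)
            m_matrix = stacks[set_id].values_matrix()
        except Exception as exc:
            log.append({"set": set_id, "scenario": "", "status": "failed", "message": str(exc)})
            continue
        for scen in layout.scenarios(set_id):
            for pct in percents:
                try:
                    g_stack = layout.load_g_stack(set_id, scen)
                    res = mop(
                        m_matrix,
                        g_stack,
                        percent=pct,
                        m_subsample=m_subsample,
                        seed=seed,
                        standardize=standardize,
                    )
                    res.scenario = scen
                    results.append(res)
                    if write_outputs:
                        d = out_root / set_id / scen
                        write_grid(res.similarity, d / f"mop_{pct:g}.asc")
                        write_grid(res.strict_mask, d / f"strict_{pct:g}.asc")
                    log.append(
                        {"set": set_id, "scenario": scen, "status": "ok", "message": f"percent={pct:g}"}
                    )
                except Exception as exc:
                    log.append(
                        {"set": set_id, "scenario": scen, "status": "failed", "message": str(exc)}
                    )
    return results, log


def mess(m_values: np.ndarray, g_stack: EnvStack) -> MessResult:
    """Multivariate environmental similarity surface.

    Per variable with M range [lo, hi] and f = percentage of M values below
    the G value:  S = 100*(g-lo)/(hi-lo) if f = 0;  2f if f <= 50;
    2*(100-f) if f < 100;  100*(hi-g)/(hi-lo) if f = 100.  The surface is
    the minimum over variables; the companion grid holds the argmin (lowest
    index on ties).
    """
    M = np.asarray(m_values, dtype=float)
    if M.size == 0:
        raise ValueError("empty calibration (M) matrix")
    if M.shape[1] != g_stack.n_layers:
        raise ValueError("variable mismatch between M matrix and G stack")
    Gmat = g_stack.values_matrix()
    n_m = M.shape[0]
    S = np.empty_like(Gmat)
    for v in range(M.shape[1]):
        mv = np.sort(M[:, v])
        lo, hi = mv[0], mv[-1]
        span = hi - lo
        g = Gmat[:, v]
        f = 100.0 * np.searchsorted(mv, g, side="left") / n_m
        with np.errstate(divide="ignore", invalid="ignore"):
            below = np.where(span > 0, 100.0 * (g - lo) / span, NEG_SENTINEL)
            above = np.where(span > 0, 100.0 * (hi - g) / span, NEG_SENTINEL)
        s = np.where(
            f == 0,
            below,
            np.where(f <= 50, 2 * f, np.where(f < 100, 2 * (100 - f), above)),
        )
        if span == 0:  # constant variable in M: inside = 100, outside = sentinel
            s = np.where(g == lo, 100.0, NEG_SENTINEL)
        S[:, v] = s
    mess_vals = S.min(axis=1)
    argmin = S.argmin(axis=1).astype(float)
    valid = ~g_stack.mask.ravel()
    full_m = np.zeros(g_stack.mask.size)
    full_m[valid] = mess_vals
    full_a = np.zeros(g_stack.mask.size)
    full_a[valid] = argmin
    return MessResult(
        mess=g_stack.grid_like(full_m),
        most_dissimilar_variable=g_stack.grid_like(full_a),
    )
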