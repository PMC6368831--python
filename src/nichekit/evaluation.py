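"""Candidate-model statistics and three-stage selection.

Three criteria rank candidates, applied hierarchically in this order:

1. **Significance** — partial ROC.  The ROC curve is restricted to the
   region with sensitivity >= 1 - E/100 and summarized as the AUC ratio
   (model partial area over null-line partial area).  Test occurrences are
   bootstrap-resampled (default 50% with replacement, 500 iterations) and
   the p-value is the direct count of iterations with AUC ratio <= 1.
2. **Performance** — omission rate at threshold E: the fraction of test
   occurrences whose suitability falls strictly below the E-th percentile
   (nearest rank) of the training-occurrence suitabilities.
3. **Complexity** — AICc from the normalized raw output at the (deduplicated)
   occurrence cells with k = number of nonzero coefficients; Delta AICc is
   recomputed *within* the significant, low-omission set (never against the
   global minimum), and candidates with Delta <= 2 are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = [
    "ProcResult",
    "OmissionResult",
    "AiccResult",
    "EvaluationRecord",
    "SelectionResult",
    "partial_roc",
    "omission_rate",
    "aicc",
    "delta_and_weights",
    "select_best",
    "evaluate_candidates",
    "plot_selection",
]

DEFAULT_E = 5.0
DEFAULT_ALPHA = 0.05
DEFAULT_DELTA_MAX = 2.0
DEFAULT_ITERATIONS = 500
DEFAULT_BOOT_FRACTION = 0.5
MAX_PROC_THRESHOLDS = 1000


@dataclass
class ProcResult:
    mean_auc_ratio: float
    p_value: float
    iterations: int
    boot_fraction: float
    E: float
    n_defined: int = 0
    diagnostic: str = ""


@dataclass
class OmissionResult:
    E: float
    threshold: float
    omission_rate: float


@dataclass
class AiccResult:
    k: int
    n: int
    log_likelihood: float
    aicc: float  # NaN when undefined (n - k - 1 <= 0)
    delta_aicc: float = float("nan")
    weight: float = float("nan")

    @property
    def defined(self) -> bool:
        return np.isfinite(self.aicc)


@dataclass
class EvaluationRecord:
    candidate_id: str
    proc: ProcResult
    omission: OmissionResult
    aicc: AiccResult
    selected_significant: bool = False
    selected_omission: bool = False
    selected_final: bool = False


@dataclass
class SelectionResult:
    selected_ids: list[str]
    tallies: dict
    fallback: bool
    status: str
    records: list[EvaluationRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Partial ROC
# ---------------------------------------------------------------------------


def _auc_ratio(area: np.ndarray, sens: np.ndarray) -> float:
    """Partial AUC ratio over a pre-restricted threshold region.

    ``area`` and ``sens`` are parallel arrays over the (ascending) threshold
    grid.  NaN when fewer than two thresholds remain or the area range is
    degenerate.
    """
    if area.size < 2:
        return float("nan")
    a = area
    s = sens
    order = np.argsort(a)
    a, s = a[order], s[order]
    if a[-1] == a[0]:
        return float("nan")
    model_area = np.trapezoid(s, a)
    null_area = 0.5 * (a[-1] ** 2 - a[0] ** 2)
    if null_area <= 0:
        return float("nan")
    return float(model_area / null_area)


def partial_roc(
    prediction: Grid | np.ndarray,
    test_suitabilities,
    E: float = DEFAULT_E,
    iterations: int = DEFAULT_ITERATIONS,
    boot_fraction: float = DEFAULT_BOOT_FRACTION,
    seed: int = 0,
) -> ProcResult:
    """Partial-ROC significance of a prediction against test occurrences.

    Thresholds are up to 1,000 evenly spaced quantiles of the prediction
    values (deduplicated), restricted once to the region where the *full*
    test set's sensitivity is >= 1 - E/100 (restricting by each bootstrap
    replicate's own sensitivity conditions on upward noise and makes the
    null anti-conservative).  For each iteration the test values are
    resampled with replacement at ``boot_fraction`` of n and the AUC ratio
    (bootstrap sensitivity vs area, over null-line area) is computed on that
    fixed region.  The p-value is the direct count of iterations with
    ratio <= 1.
    """
    if isinstance(prediction, Grid):
        pred_vals = prediction.unmasked()
    else:
        pred_vals = np.asarray(prediction, dtype=float).ravel()
    test = np.asarray(test_suitabilities, dtype=float).ravel()
    if test.size < 2:
        raise ValueError("need at least 2 test suitability values")
    if np.unique(pred_vals).size < 2:
        raise ValueError("prediction must have at least 2 distinct values")
    if not (0 < boot_fraction <= 1):
        raise ValueError("boot_fraction must be in (0, 1]")
    qs = np.linspace(0, 1, MAX_PROC_THRESHOLDS)
    thresholds = np.unique(np.quantile(pred_vals, qs))
    # fraction of cells with prediction >= t, per ascending threshold
    sorted_pred = np.sort(pred_vals)
    area = 1.0 - np.searchsorted(sorted_pred, thresholds, side="left") / sorted_pred.size
    min_sens = 1.0 - E / 100.0
    sorted_test = np.sort(test)
    sens_full = 1.0 - np.searchsorted(sorted_test, thresholds, side="left") / test.size
    keep = sens_full >= min_sens
    rng = np.random.default_rng(seed)
    m = max(1, round(boot_fraction * test.size))
    ratios = np.empty(iterations)
    for it in range(iterations):
        boot = test[rng.integers(0, test.size, size=m)]
        boot.sort()
        sens = 1.0 - np.searchsorted(boot, thresholds, side="left") / m
        ratios[it] = _auc_ratio(area[keep], sens[keep])
    defined = np.isfinite(ratios)
    n_defined = int(defined.sum())
    diagnostic = ""
    if n_defined == 0:
        diagnostic = "no threshold satisfied the sensitivity restriction"
        warnings.warn("partial ROC undefined: " + diagnostic, stacklevel=2)
        return ProcResult(float("nan"), 1.0, iterations, boot_fraction, E, 0, diagnostic)
    if n_defined < iterations:
        diagnostic = f"{iterations - n_defined} iteration(s) with undefined ratio"
    # undefined iterations count as non-significant in the direct-count p
    p = float((np.sum(ratios[defined] <= 1.0) + (iterations - n_defined)) / iterations)
    return ProcResult(
        mean_auc_ratio=float(np.mean(ratios[defined])),
        p_value=p,
        iterations=iterations,
        boot_fraction=boot_fraction,
        E=E,
        n_defined=n_defined,
        diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# Omission rate
# ---------------------------------------------------------------------------


def omission_rate(
    train_suitabilities, test_suitabilities, E: float = DEFAULT_E
) -> OmissionResult:
    """Omission of test occurrences at the E% training threshold.

    Threshold = nearest-rank E-th percentile of the training suitabilities
    (rank = ceil(E/100 * n_train); rank 0 maps to the minimum); ties at the
    threshold count as not omitted.
    """
    train = np.sort(np.asarray(train_suitabilities, dtype=float).ravel())
    test = np.asarray(test_suitabilities, dtype=float).ravel()
    if train.size == 0 or test.size == 0:
        raise ValueError("empty suitability list")
    if not (0 <= E < 100):
        raise ValueError("E must be in [0, 100)")
    rank = int(np.ceil(E / 100.0 * train.size))
    threshold = float(train[max(rank, 1) - 1])
    rate = float(np.mean(test < threshold))
    return OmissionResult(E=E, threshold=threshold, omission_rate=rate)


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------


def aicc(
    raw_prediction: Grid | np.ndarray,
    occurrence_cells: np.ndarray,
    k: int,
) -> AiccResult:
    """AICc from the normalized raw output at (deduplicated) occurrence cells.

    ``occurrence_cells`` indexes the flattened grid (Grid input) or the value
    vector directly (array input).  AICc is undefined when n - k - 1 <= 0.
    """
    if isinstance(raw_prediction, Grid):
        flat = raw_prediction.values.ravel()
        mask = raw_prediction.nodata_mask.ravel()
        if np.any(mask[occurrence_cells]):
            raise ValueError("occurrence on a masked cell")
        total = flat[~mask].sum()
    else:
        flat = np.asarray(raw_prediction, dtype=float).ravel()
        total = flat.sum()
    cells = np.unique(np.asarray(occurrence_cells, dtype=int))
    n = cells.size
    raw = flat[cells] / total  # defensive renormalization
    if np.any(raw <= 0):
        log_l = -np.inf
    else:
        log_l = float(np.sum(np.log(raw)))
    if n - k - 1 <= 0 or not np.isfinite(log_l):
        return AiccResult(k=k, n=n, log_likelihood=log_l, aicc=float("nan"))
    value = 2 * k - 2 * log_l + (2 * k * (k + 1)) / (n - k - 1)
    return AiccResult(k=k, n=n, log_likelihood=log_l, aicc=float(value))


def delta_and_weights(aiccs) -> tuple[np.ndarray, np.ndarray]:
    """Delta AICc and Akaike weights for a set of defined AICc values."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("need at least one defined (finite) AICc value")
    deltas = a - a.min()
    w = np.exp(-deltas / 2.0)
    return deltas, w / w.sum()


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select_best(
    records: list[EvaluationRecord],
    alpha: float = DEFAULT_ALPHA,
    E: float = DEFAULT_E,
    delta_max: float = DEFAULT_DELTA_MAX,
) -> SelectionResult:
    """Hierarchical selection: significance, then omission, then Delta AICc.

    Stage 2 falls back to the minimum-omission significant models when no
    significant model meets omission <= E/100.  Stage 3 recomputes Delta
    within the surviving set (reference = minimum AICc among significant,
    low-omission candidates, never the global minimum); candidates with
    undefined AICc survive stages 1-2 but cannot be selected at stage 3.
    """
    if not records:
        raise ValueError("no evaluation records")
    for r in records:
        r.selected_significant = r.selected_omission = r.selected_final = False
    sig = [r for r in records if r.proc.p_value < alpha]
    for r in sig:
        r.selected_significant = True
    fallback = False
    if not sig:
        return SelectionResult(
            selected_ids=[],
            tallies={
                "candidates": len(records),
                "significant": 0,
                "low_omission": 0,
                "selected": 0,
            },
            fallback=False,
            status="no significant models",
            records=records,
        )
    low_om = [r for r in sig if r.omission.omission_rate <= E / 100.0]
    if not low_om:
        fallback = True
        min_om = min(r.omission.omission_rate for r in sig)
        low_om = [r for r in sig if r.omission.omission_rate == min_om]
    for r in low_om:
        r.selected_omission = True
    defined = [r for r in low_om if r.aicc.defined]
    if defined:
        deltas, weights = delta_and_weights([r.aicc.aicc for r in defined])
        for r, d, w in zip(defined, deltas, weights):
            r.aicc.delta_aicc = float(d)
            r.aicc.weight = float(w)
            if d <= delta_max:
                r.selected_final = True
    selected = [r.candidate_id for r in records if r.selected_final]
    status = "ok" if selected else "no model met the Delta AICc criterion"
    if fallback:
        status += " (omission fallback: no significant model met omission <= E)"
    return SelectionResult(
        selected_ids=selected,
        tallies={
            "candidates": len(records),
            "significant": len(sig),
            "low_omission": len(low_om),
            "selected": len(selected),
        },
        fallback=fallback,
        status=status,
        records=records,
    )


# ---------------------------------------------------------------------------
# Batch evaluation of calibration output
# ---------------------------------------------------------------------------


def evaluate_candidates(
    pairs,
    layout,
    *,
    E: float = DEFAULT_E,
    alpha: float = DEFAULT_ALPHA,
    delta_max: float = DEFAULT_DELTA_MAX,
    iterations: int = DEFAULT_ITERATIONS,
    boot_fraction: float = DEFAULT_BOOT_FRACTION,
    seed: int = 0,
    stacks: dict | None = None,
    write_outputs: bool = True,
) -> tuple[pd.DataFrame, SelectionResult]:
    """Compute all three statistics for fitted candidate pairs and select.

    Writes ``calibration_results.csv``, ``selected_models.csv`` and
    ``selection_summary.txt`` under the project root, plus the
    omission-vs-AICc diagnostic figure.
    """
    from .engine import predict, predict_values
    from .grids import extract_values, occurrence_cells

    occ_joint = layout.load_occurrences("joint")
    occ_train = layout.load_occurrences("train")
    occ_test = layout.load_occurrences("test")
    if stacks is None:
        stacks = {}
    records: list[EvaluationRecord] = []
    for i, pair in enumerate(pairs):
        set_id = pair.spec.set_id
        if set_id not in stacks:
            stacks[set_id] = layout.load_m_stack(set_id)
        stack = stacks[set_id]
        pred_train = predict(pair.model_train, stack, output="logistic", mode="free")
        test_vals = extract_values(pred_train, occ_test)
        train_vals = extract_values(pred_train, occ_train)
        proc = partial_roc(
            pred_train,
            test_vals,
            E=E,
            iterations=iterations,
            boot_fraction=boot_fraction,
            seed=(seed + 7919 * i) % (2**31),
        )
        om = omission_rate(train_vals, test_vals, E=E)
        pred_full_raw = predict(pair.model_full, stack, output="raw", mode="free")
        cells = occurrence_cells(stack, occ_joint, dedupe=True)
        ic = aicc(pred_full_raw, cells, pair.model_full.n_parameters)
        records.append(
            EvaluationRecord(pair.spec.candidate_id, proc, om, ic)
        )
    selection = select_best(records, alpha=alpha, E=E, delta_max=delta_max)
    table = records_to_frame(records)
    if write_outputs:
        root = Path(layout.root)
        table.to_csv(root / "calibration_results.csv", index=False)
        table[table["selected"]].to_csv(root / "selected_models.csv", index=False)
        _write_summary(root / "selection_summary.txt", selection, alpha, E, delta_max)
        try:
            plot_selection(records, root / "selection_plot.png")
        except Exception as exc:  # plotting must never sink a run
            warnings.warn(f"selection plot failed: {exc}", stacklevel=2)
    return table, selection


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate_id": [r.candidate_id for r in records],
            "mean_auc_ratio": [r.proc.mean_auc_ratio for r in records],
            "p_value": [r.proc.p_value for r in records],
            "omission_rate": [r.omission.omission_rate for r in records],
            "aicc": [r.aicc.aicc for r in records],
            "delta_aicc": [r.aicc.delta_aicc for r in records],
            "weight_aicc": [r.aicc.weight for r in records],
            "n_parameters": [r.aicc.k for r in records],
            "significant": [r.selected_significant for r in records],
            "low_omission": [r.selected_omission for r in records],
            "selected": [r.selected_final for r in records],
        }
    )


def _write_summary(path, selection: SelectionResult, alpha, E, delta_max) -> None:
    t = selection.tallies
    lines = [
        "Model selection summary",
        "=======================",
        f"criteria: p < {alpha} (partial ROC), omission rate <= {E}% , Delta AICc <= {delta_max}",
        f"candidate models evaluated: {t['candidates']}",
        f"statistically significant: {t['significant']}",
        f"meeting omission criterion: {t['low_omission']}"
        + ("  [fallback: minimum-omission set]" if selection.fallback else ""),
        f"selected (Delta AICc <= {delta_max}): {t['selected']}",
        f"status: {selection.status}",
        "",
        "selected models:",
    ] + [f"  {cid}" for cid in selection.selected_ids]
    Path(path).write_text("\n".join(lines) + "\n")


def plot_selection(records: list[EvaluationRecord], path) -> None:
    """Omission-vs-AICc diagnostic scatter: all / non-significant / selected."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x_all = [r.aicc.aicc for r in records]
    y_all = [r.omission.omission_rate for r in records]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(x_all, y_all, s=18, c="#777777", label="all candidate models")
    ns = [r for r in records if not r.selected_significant]
    ax.scatter(
        [r.aicc.aicc for r in ns],
        [r.omission.omission_rate for r in ns],
        s=18,
        c="#d95f02",
        label="non-significant",
    )
    sel = [r for r in records if r.selected_final]
    ax.scatter(
        [r.aicc.aicc for r in sel],
        [r.omission.omission_rate for r in sel],
        s=40,
        marker="D",
        c="#1b9e77",
        label="selected",
    )
    ax.set_xlabel("AICc")
    ax.set_ylabel(f"omission rate at E = {records[0].omission.E:g}%")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
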