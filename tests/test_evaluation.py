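"""Partial ROC, omission, AICc, and the three-stage selection rule."""

import numpy as np
import pytest

from nichekit.evaluation import (
    AiccResult,
    EvaluationRecord,
    OmissionResult,
    ProcResult,
    aicc,
    delta_and_weights,
    omission_rate,
    partial_roc,
    select_best,
)

from conftest import make_grid


# ---------------------------------------------------------------------------
# partial ROC
# ---------------------------------------------------------------------------


class TestPartialRoc:
    def test_perfect_discrimination_p_zero(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(size=1000)
        res = partial_roc(pred, [pred.max()] * 10, E=5, iterations=200, seed=1)
        assert res.p_value == 0.0
        assert res.mean_auc_ratio > 1.0

    def test_parameters_stored_verbatim(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(size=500)
        res = partial_roc(pred, pred[:20], E=5, iterations=500, boot_fraction=0.5, seed=0)
        assert res.iterations == 500
        assert res.boot_fraction == 0.5
        assert res.E == 5

    def test_null_model_ratio_near_one(self):
        """Uniform prediction + uniformly placed test points: the partial AUC
        ratio has no discrimination to reward, so its mean sits at 1."""
        rng = np.random.default_rng(123)
        pred = rng.uniform(size=2500)
        test = rng.choice(pred, size=50)
        res = partial_roc(pred, test, E=5, iterations=500, boot_fraction=0.5, seed=3)
        assert abs(res.mean_auc_ratio - 1.0) < 0.05

    def test_null_false_positive_rate_bounded(self):
        """Calibration: across 40 independent uniform-null models, at most
        10% may come out significant at alpha = 0.05."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pred = rng.uniform(size=2500)
            test = rng.choice(pred, size=50)
            res = partial_roc(pred, test, E=5, iterations=500, boot_fraction=0.5, seed=seed)
            hits += res.p_value < 0.05
        assert hits / 40 <= 0.10

    def test_degenerate_restriction_is_diagnosed(self):
        # all test values below every prediction value: sensitivity never
        # reaches 1 - E/100 except at the very bottom threshold
        pred = np.linspace(0.5, 1.0, 200)
        with pytest.warns(UserWarning, match="undefined"):
            res = partial_roc(np.r_[pred, 0.4], [0.1, 0.2], E=5, iterations=50, seed=0)
        assert np.isnan(res.mean_auc_ratio)
        assert res.p_value == 1.0

    def test_grid_input_uses_unmasked_cells(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(20, 20))
        grid = make_grid(vals)
        res_g = partial_roc(grid, vals.ravel()[:30], E=5, iterations=100, seed=2)
        res_a = partial_roc(vals.ravel(), vals.ravel()[:30], E=5, iterations=100, seed=2)
        assert res_g.mean_auc_ratio == res_a.mean_auc_ratio


# ---------------------------------------------------------------------------
# omission rate
# ---------------------------------------------------------------------------


class TestOmission:
    def test_zero_E_threshold_is_minimum(self):
        train = np.linspace(0.2, 0.9, 10)
        res = omission_rate(train, train, E=0)
        assert res.threshold == 0.2
        assert res.omission_rate == 0.0

    def test_nearest_rank_example(self):
        train = np.arange(0.1, 1.01, 0.1)
        res = omission_rate(train, [0.05, 0.5], E=5)
        assert res.threshold == pytest.approx(0.1)  # rank ceil(0.5) = 1
        assert res.omission_rate == 0.5

    def test_tie_at_threshold_not_omitted(self):
        res = omission_rate([0.3, 0.5, 0.7], [0.3, 0.29], E=40)  # rank 2 -> 0.5? no: ceil(1.2)=2
        assert res.threshold == 0.5
        assert res.omission_rate == 1.0
        res2 = omission_rate([0.3, 0.5, 0.7], [0.5, 0.49], E=40)
        assert res2.omission_rate == 0.5  # 0.5 ties the threshold, not omitted

    def test_monotone_in_E(self):
        rng = np.random.default_rng(4)
        train = rng.uniform(size=40)
        test = rng.uniform(size=25)
        rates = [omission_rate(train, test, E=e).omission_rate for e in range(21)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            omission_rate([], [0.1], E=5)


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------


class TestAicc:
    def test_uniform_closed_form(self):
        C, n = 16, 5
        raw = np.full(C, 1.0 / C)
        res = aicc(raw, np.arange(n), k=0)
        assert res.aicc == pytest.approx(2 * n * np.log(C))
        assert res.log_likelihood == pytest.approx(-n * np.log(C))

    def test_guard_n_minus_k_minus_1(self):
        raw = np.array([0.4, 0.3, 0.2, 0.1])
        res = aicc(raw, [0, 1], k=1)  # n = 2, n - k - 1 = 0
        assert res.log_likelihood == pytest.approx(np.log(0.4) + np.log(0.3))
        assert not res.defined

    def test_k_equal_n_undefined(self):
        raw = np.full(8, 1 / 8)
        assert not aicc(raw, [0, 1, 2], k=3).defined

    def test_occurrences_deduplicated(self):
        raw = np.array([0.5, 0.5])
        res = aicc(raw, [0, 0, 0, 1], k=0)
        assert res.n == 2

    def test_masked_occurrence_rejected(self):
        g = make_grid([[0.5, 0.5]], mask=[[True, False]])
        with pytest.raises(ValueError, match="masked"):
            aicc(g, [0], k=0)

    def test_delta_and_weights_basics(self):
        d, w = delta_and_weights([100.0])
        assert d[0] == 0 and w[0] == 1
        d, w = delta_and_weights([50.0, 50.0])
        assert np.allclose(w, [0.5, 0.5])
        assert np.isclose(w.sum(), 1.0, atol=1e-12)

    def test_printed_candidate_table_deltas(self):
        """Published candidate AICc columns for a tick ENM reproduce the
        printed Delta values at two-decimal rounding."""
        d, _ = delta_and_weights([3346.46, 3385.65, 3358.27, 3348.13])
        assert np.round(d, 2).tolist() == [0.0, 39.19, 11.81, 1.67]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            delta_and_weights([])


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def make_record(cid, p, om, aicc_val, k=3):
    return EvaluationRecord(
        candidate_id=cid,
        proc=ProcResult(1.5, p, 100, 0.5, 5.0),
        omission=OmissionResult(5.0, 0.1, om),
        aicc=AiccResult(k=k, n=50, log_likelihood=-100.0, aicc=aicc_val),
    )


def brute_force_select(records, alpha=0.05, E=5.0, delta_max=2.0):
    """Independent rule-by-rule reimplementation of the selection logic."""
    sig = {r.candidate_id for r in records if r.proc.p_value < alpha}
    if not sig:
        return set(), False
    low = {
        r.candidate_id
        for r in records
        if r.candidate_id in sig and r.omission.omission_rate <= E / 100
    }
    fallback = False
    if not low:
        fallback = True
        best = min(r.omission.omission_rate for r in records if r.candidate_id in sig)
        low = {
            r.candidate_id
            for r in records
            if r.candidate_id in sig and r.omission.omission_rate == best
        }
    pool = [r for r in records if r.candidate_id in low and np.isfinite(r.aicc.aicc)]
    if not pool:
        return set(), fallback
    ref = min(r.aicc.aicc for r in pool)
    return {r.candidate_id for r in pool if r.aicc.aicc - ref <= delta_max}, fallback


def random_records(rng, n):
    recs = []
    for i in range(n):
        a = rng.uniform(100, 120) if rng.uniform() > 0.1 else float("nan")
        recs.append(
            make_record(
                f"c{i}",
                p=float(rng.choice([0.0, 0.02, 0.04, 0.06, 0.5])),
                om=float(rng.choice([0.0, 0.03, 0.05, 0.08, 0.2])),
                aicc_val=a,
            )
        )
    return recs


class TestSelection:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            recs = random_records(rng, int(rng.integers(1, 12)))
            got = select_best(recs)
            want, fb = brute_force_select(recs)
            assert set(got.selected_ids) == want
            assert got.fallback == fb

    def test_stage_nesting(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            recs = random_records(rng, 8)
            select_best(recs)
            for r in recs:
                if r.selected_final:
                    assert r.selected_omission
                if r.selected_omission:
                    assert r.selected_significant

    def test_global_minimum_of_nonsignificant_model_ignored(self):
        """A non-significant model with the globally minimal AICc must not
        set the Delta reference for the surviving pool."""
        recs = [
            make_record("global_min", p=0.5, om=0.0, aicc_val=100.0),
            make_record("good_a", p=0.0, om=0.0, aicc_val=110.0),
            make_record("good_b", p=0.0, om=0.0, aicc_val=111.5),
            make_record("good_far", p=0.0, om=0.0, aicc_val=120.0),
        ]
        res = select_best(recs)
        assert set(res.selected_ids) == {"good_a", "good_b"}

    def test_all_significant_zero_omission_equal_aicc_all_selected(self):
        recs = [make_record(f"c{i}", 0.0, 0.0, 100.0) for i in range(4)]
        res = select_best(recs)
        assert len(res.selected_ids) == 4

    def test_no_significant_is_status_not_exception(self):
        recs = [make_record("a", 0.9, 0.0, 100.0)]
        res = select_best(recs)
        assert res.selected_ids == []
        assert "significant" in res.status
        assert res.tallies["significant"] == 0

    def test_omission_fallback_flagged(self):
        recs = [
            make_record("a", 0.0, 0.3, 100.0),
            make_record("b", 0.0, 0.2, 105.0),
        ]
        res = select_best(recs)
        assert res.fallback
        assert res.selected_ids == ["b"]

    def test_undefined_aicc_survives_stages_but_not_selected(self):
        recs = [
            make_record("defined", 0.0, 0.0, 100.0),
            make_record("undefined", 0.0, 0.0, float("nan")),
        ]
        res = select_best(recs)
        undef = [r for r in recs if r.candidate_id == "undefined"][0]
        assert undef.selected_omission
        assert not undef.selected_final
        assert res.selected_ids == ["defined"]

    def test_weights_renormalized_within_pool(self):
        recs = [
            make_record("x", 0.0, 0.0, 100.0),
            make_record("y", 0.0, 0.0, 101.0),
            make_record("excluded", 0.5, 0.0, 90.0),
        ]
        select_best(recs)
        w = [r.aicc.weight for r in recs if r.selected_omission]
        assert np.isclose(np.nansum(w), 1.0, atol=1e-12)
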