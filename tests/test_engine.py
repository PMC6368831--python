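"""The penalized Gibbs engine: fitting, penalties, outputs, extrapolation."""

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from nichekit.engine import (
    GibbsModel,
    count_parameters,
    fit,
    fit_replicates,
    fit_stack,
    predict,
    predict_values,
)
from nichekit.features import FeatureSpec
from nichekit.grids import OccurrenceSet

from conftest import make_stack


@pytest.fixture(scope="module")
def background():
    rng = np.random.default_rng(7)
    return rng.uniform(size=(800, 2))


class TestFit:
    def test_null_fit_shrinks_to_uniform(self, background):
        """Presences drawn uniformly from the background carry no signal, so
        the L1 penalty at rm=1 zeroes every coefficient and the raw output
        is uniform over the background cells."""
        rng = np.random.default_rng(11)
        pres = background[rng.choice(len(background), size=10, replace=False)]
        model = fit(pres, background, rm=1.0, spec=FeatureSpec(("l", "q")))
        assert np.all(np.abs(model.coefficients) <= 1e-3)
        raw = predict_values(model, background, output="raw")
        assert np.allclose(raw, 1.0 / len(background), rtol=0.05)

    def test_huge_rm_gives_all_exact_zeros(self, background):
        rng = np.random.default_rng(3)
        pres = background[:50] ** 0.2  # strongly non-uniform presences
        model = fit(pres, background, rm=1e6, spec=FeatureSpec(("l", "q")))
        assert count_parameters(model) == 0
        assert np.all(model.coefficients == 0.0)

    def test_sign_recovery_monotone_sample(self, background):
        """Presences concentrated at high values of variable 1 must get a
        positive linear coefficient on that variable."""
        order = np.argsort(background[:, 0])
        pres = background[order[-40:]]
        model = fit(pres, background, rm=1.0, spec=FeatureSpec(("l",)))
        assert model.coefficients[0] > 0

    def test_penalty_monotone_at_extremes(self, background):
        order = np.argsort(background[:, 0])
        pres = background[order[-40:]]
        spec = FeatureSpec(("l", "q"))
        k_small = count_parameters(fit(pres, background, rm=0.1, spec=spec))
        k_huge = count_parameters(fit(pres, background, rm=1e6, spec=spec))
        assert k_huge == 0
        assert k_huge <= k_small

    def test_too_few_presences_rejected(self, background):
        with pytest.raises(ValueError, match="presence"):
            fit(background[:1], background, rm=1.0, spec=FeatureSpec(("l",)))

    def test_count_never_exceeds_features(self, background):
        pres = background[:30]
        model = fit(pres, background, rm=0.1, spec=FeatureSpec(("l", "q", "p")))
        assert 0 <= count_parameters(model) <= len(model.feature_defs)


class TestNormalizationAndOutputs:
    @pytest.mark.parametrize("fc", ["lq", "lqp", "lqph", "lqpth"])
    def test_raw_sums_to_one_over_calibration(self, default_species, fc):
        _, stack, _, occs = default_species
        spec = FeatureSpec.from_label(fc, threshold_knots=5, hinge_knots=5)
        model = fit_stack(occs["train"], stack, 1.0, spec, background_size=1000, seed=2)
        raw = predict(model, stack, output="raw")
        assert abs(raw.unmasked().sum() - 1.0) < 1e-8

    def test_output_transforms_share_ranking(self, default_species):
        _, stack, _, occs = default_species
        model = fit_stack(occs["train"], stack, 1.0, FeatureSpec(("l", "q")),
                          background_size=1000, seed=2)
        raw = predict(model, stack, "raw").unmasked()
        logi = predict(model, stack, "logistic").unmasked()
        clog = predict(model, stack, "cloglog").unmasked()
        assert np.array_equal(rankdata(raw), rankdata(logi))
        assert np.array_equal(rankdata(raw), rankdata(clog))
        assert np.all((logi >= 0) & (logi <= 1))
        assert np.all((clog >= 0) & (clog <= 1))

    def test_virtual_species_recovery(self, default_species):
        """Predicted suitability must rank cells like the true suitability."""
        _, stack, suit, occs = default_species
        model = fit_stack(occs["joint"], stack, 1.0, FeatureSpec(("l", "q")),
                          background_size=2000, seed=1)
        pred = predict(model, stack, "logistic")
        rho = spearmanr(pred.unmasked(), suit.unmasked()).statistic
        assert rho >= 0.7


@pytest.fixture(scope="module")
def fitted(default_species):
    _, stack, _, occs = default_species
    model = fit_stack(occs["train"], stack, 1.0, FeatureSpec(("l", "q")),
                      background_size=1000, seed=2)
    return model, stack


class TestExtrapolationModes:
    def test_identical_env_all_modes_agree(self, fitted):
        model, stack = fitted
        grids = [predict(model, stack, "logistic", mode=m) for m in ("free", "clamp", "none")]
        assert np.allclose(grids[0].values, grids[1].values)
        assert np.allclose(grids[0].values, grids[2].values)

    def test_none_zeroes_out_of_range(self, fitted):
        model, _ = fitted
        lo, hi = model.ranges[0]
        inside = [(lo + hi) / 2, (model.ranges[1][0] + model.ranges[1][1]) / 2, 0.5]
        outside = list(inside)
        outside[0] = hi + 0.1 * (hi - lo)
        vals = predict_values(model, [inside, outside], "cloglog", mode="none")
        assert vals[0] > 0
        assert vals[1] == 0.0

    def test_clamp_equals_boundary_value(self, fitted):
        model, _ = fitted
        lo, hi = model.ranges[0]
        mid2 = (model.ranges[1][0] + model.ranges[1][1]) / 2
        at_max = [hi, mid2, 0.5]
        beyond = [hi + 123.0, mid2, 0.5]
        v1 = predict_values(model, [at_max], "raw", mode="clamp")
        v2 = predict_values(model, [beyond], "raw", mode="clamp")
        assert np.isclose(v1[0], v2[0])

    def test_missing_variable_named(self, fitted):
        model, stack = fitted
        partial = make_stack([g.values for g in stack.layers[:2]], names=stack.names[:2],
                             transform=stack.transform)
        with pytest.raises(ValueError, match="env_3"):
            predict(model, partial)


class TestReplicatesAndSerialization:
    def test_replicates_deterministic_and_counted(self, default_species):
        _, stack, _, occs = default_species
        occ = OccurrenceSet(occs["train"].species, occs["train"].records[:60], "train")
        spec = FeatureSpec(("l",))
        reps1 = fit_replicates(occ, stack, 1.0, spec, n_reps=3, seed=5, background_size=500)
        reps2 = fit_replicates(occ, stack, 1.0, spec, n_reps=3, seed=5, background_size=500)
        assert len(reps1) == 3
        for a, b in zip(reps1, reps2):
            assert np.array_equal(a.coefficients, b.coefficients)
        reps3 = fit_replicates(occ, stack, 1.0, spec, n_reps=3, seed=6, background_size=500)
        assert any(
            not np.array_equal(a.coefficients, b.coefficients)
            for a, b in zip(reps1, reps3)
        )

    def test_json_roundtrip_preserves_predictions(self, default_species, tmp_path):
        _, stack, _, occs = default_species
        model = fit_stack(occs["train"], stack, 1.0, FeatureSpec(("l", "q")),
                          background_size=500, seed=2)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = GibbsModel.load(path)
        a = predict(model, stack, "logistic").values
        b = predict(loaded, stack, "logistic").values
        assert np.allclose(a, b)
        assert loaded.n_parameters == model.n_parameters
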