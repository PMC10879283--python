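import numpy as np
import pandas as pd
import pytest

from ftdx import default_atlas_schema, integrated_gradients
from ftdx.attribution import (
    completeness_residual,
    export_importance_tables,
    population_importance_map,
    subject_attributions,
)
from ftdx.classifier import ParallelEmbeddingClassifier
from ftdx.crossval import N_INNER, TrainedEnsemble


class TestIntegratedGradientsCore:
    def test_linear_model_closed_form(self, rng):
        """For F(x) = w.x + b and zero baseline, IG_i = w_i x_i exactly,
        independent of step count."""
        w = rng.standard_normal(10)
        x = rng.standard_normal(10)
        grad_fn = lambda batch: np.tile(w, (batch.shape[0], 1))
        for steps in (1, 3, 64):
            attr = integrated_gradients(grad_fn, x, np.zeros(10), steps=steps)
            np.testing.assert_allclose(attr, w * x, atol=1e-12)

    def test_baseline_at_input_gives_zero(self, rng):
        x = rng.standard_normal(7)
        grad_fn = lambda batch: batch**2 + 1.0
        attr = integrated_gradients(grad_fn, x, x.copy(), steps=16)
        np.testing.assert_allclose(attr, 0.0)

    def test_quadratic_analytic_integral(self):
        """F(x) = x^2 scalar: IG = x^2; midpoint rule at 256 steps
        matches the analytic value to 1e-4."""
        x = np.array([1.7])
        grad_fn = lambda batch: 2.0 * batch  # dF/dx = 2x along the path
        attr = integrated_gradients(grad_fn, x, np.zeros(1), steps=256)
        assert attr[0] == pytest.approx(x[0] ** 2, abs=1e-4)

    def test_invalid_arguments(self):
        grad_fn = lambda b: b
        with pytest.raises(ValueError, match="steps"):
            integrated_gradients(grad_fn, np.ones(3), np.zeros(3), steps=0)
        with pytest.raises(ValueError, match="shape"):
            integrated_gradients(grad_fn, np.ones(3), np.zeros(4))
        bad_fn = lambda b: np.full_like(b, np.nan)
        with pytest.raises(FloatingPointError):
            integrated_gradients(bad_fn, np.ones(3), np.zeros(3))


@pytest.fixture(scope="module")
def trained_ensemble():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((60, 735))
    X[:20, :15] -= 2.5; X[20:40, 380:395] -= 2.5; X[40:, 50:65] -= 2.5
    y = np.array(["bvFTD"] * 20 + ["nfvPPA"] * 20 + ["svPPA"] * 20)
    members = [
        ParallelEmbeddingClassifier(max_epochs=40, random_state=s).fit(X, y)
        for s in range(N_INNER)
    ]
    return TrainedEnsemble(members, None, 0), X, y


class TestNetworkAttribution:
    def test_completeness_on_trained_network(self, trained_ensemble, rng):
        """Sum of attributions approaches F_c(x) - F_c(baseline):
        residual < 1% of the logit gap at 256 steps."""
        ens, X, _ = trained_ensemble
        net = ens.members[0].net_
        baseline = np.zeros(735)
        for i in range(3):
            x = X[i]
            gap = abs(
                net.predict_logits(x[None])[0, 0]
                - net.predict_logits(baseline[None])[0, 0]
            )
            res = completeness_residual(net, x, baseline, 0, steps=256)
            assert res < max(0.01 * gap, 1e-6)

    def test_logit_offset_invariance(self, trained_ensemble):
        """Adding a constant to all logits (via output biases) leaves
        attributions unchanged."""
        ens, X, _ = trained_ensemble
        net = ens.members[0].net_
        grad_fn = lambda b: net.input_gradients(b, 2)
        a1 = integrated_gradients(grad_fn, X[0], np.zeros(735), steps=32)
        net.out.b += 13.0
        a2 = integrated_gradients(grad_fn, X[0], np.zeros(735), steps=32)
        net.out.b -= 13.0
        np.testing.assert_allclose(a1, a2, atol=1e-10)

    def test_batched_attributions_match_reference_loop(self, trained_ensemble):
        """The vectorized population path agrees with the single-subject
        reference implementation."""
        ens, X, _ = trained_ensemble
        got = subject_attributions(ens, X[:3], target_class=1, steps=16)
        baseline = np.zeros(735)
        for i in range(3):
            ref = np.mean(
                [
                    integrated_gradients(
                        lambda b: m.net_.input_gradients(b, 1),
                        X[i], baseline, steps=16,
                    )
                    for m in ens.members
                ],
                axis=0,
            )
            np.testing.assert_allclose(got[i], ref, atol=1e-10)


class TestPopulationMaps:
    def _wtable(self, X, y):
        from ftdx.tables import FeatureTable

        schema = default_atlas_schema()
        meta = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(y))],
                "diagnosis": y,
                "age": 60.0, "sex": "M", "education": 16.0,
                "tiv": 1.4e6, "cohort": "A", "scanner_id": "A1",
            }
        )
        return FeatureTable(
            metadata=meta,
            features=pd.DataFrame(X, columns=schema.feature_names),
            schema=schema,
            harmonized=True,
        )

    def test_single_subject_map_equals_plain_ig(self, trained_ensemble):
        ens, X, y = trained_ensemble
        table = self._wtable(X[:1], ["bvFTD"])
        baseline = np.zeros(735)
        m = population_importance_map(
            ens, table, "bvFTD", steps=16, baseline=baseline
        )
        direct = subject_attributions(ens, X[:1], 0, steps=16)[0]
        np.testing.assert_allclose(m["all"], direct, atol=1e-12)
        assert m["thickness"].shape == (360,)
        assert m["subcortical_volume"].shape == (15,)

    def test_requires_harmonized_table_and_subjects(self, trained_ensemble):
        ens, X, y = trained_ensemble
        table = self._wtable(X, y)
        table.harmonized = False
        with pytest.raises(ValueError, match="harmonized"):
            population_importance_map(ens, table, "bvFTD", steps=4)
        table.harmonized = True
        only_bv = self._wtable(X[:20], y[:20])
        with pytest.raises(ValueError, match="svPPA"):
            population_importance_map(ens, only_bv, "svPPA", steps=4)

    def test_export_table_shape_and_round_trip(
        self, trained_ensemble, tmp_path
    ):
        ens, X, y = trained_ensemble
        table = self._wtable(X, y)
        maps = {
            dx: population_importance_map(ens, table, dx, steps=8)
            for dx in ("bvFTD", "svPPA")
        }
        out = tmp_path / "importance.csv"
        df = export_importance_tables(maps, table.schema, out)
        assert len(df) == 360 + 360 + 15
        back = pd.read_csv(out)
        np.testing.assert_allclose(
            back["attribution_bvFTD"],
            maps["bvFTD"]["all"][df["index"]],
            rtol=1e-4,
        )

    def test_planted_features_dominate_attributions(self, trained_ensemble):
        """Features carrying the class signal receive the largest
        population-mean |IG| for that class."""
        ens, X, y = trained_ensemble
        table = self._wtable(X, y)
        m = population_importance_map(ens, table, "svPPA", steps=32)
        top = np.argsort(np.abs(m["thickness"]))[::-1][:15]
        planted = set(range(50, 65))
        assert len(planted & set(top)) >= 10
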