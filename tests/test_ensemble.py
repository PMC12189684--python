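"""AUC gating, weighted averaging, importance, and response curves."""

import numpy as np
import pandas as pd
import pytest

from loligosdm import (
    EvalReport,
    build_ensemble,
    ensemble_predict,
    fit,
    predict,
    response_curve,
    select_members,
    split,
    variable_importance,
)
from loligosdm.ensemble import EmptyEnsembleError, EnsembleModel


def report(algo, auc):
    return EvalReport(algorithm=algo, auc=auc, tss=0.5,
                      optimal_threshold=0.5, split_seed=0, test_fraction=0.2)


class TestGate:
    def test_gate_at_0_8(self):
        reports = [report("RF", 0.95), report("GLM", 0.85), report("SRE", 0.79)]
        sel = select_members(reports, auc_min=0.8)
        assert [r.algorithm for r in sel] == ["RF", "GLM"]

    def test_exactly_0_8_excluded(self):
        reports = [report("RF", 0.9), report("GLM", 0.8)]
        sel = select_members(reports)
        assert [r.algorithm for r in sel] == ["RF"]

    def test_all_below_gate_raises(self):
        with pytest.raises(EmptyEnsembleError):
            select_members([report("RF", 0.7), report("GLM", 0.6)])

    def test_no_reports_rejected(self):
        with pytest.raises(ValueError):
            select_members([])


class _ConstantModel:
    """Stub member emitting a fixed probability everywhere."""

    def __init__(self, p, covariates=("sbt",)):
        self.p = p
        self.algorithm = f"const{p}"
        self.covariates = list(covariates)
        self.training_range = {c: (0.0, 1.0) for c in covariates}

    def predict(self, rows):
        return np.full(len(rows), self.p)


def _stub_predict(members, weights, rows):
    preds = np.stack([m.predict(rows) for m in members])
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return w @ preds


class TestWeightedAverage:
    rows = pd.DataFrame({"sbt": [18.0, 20.0, 22.0]})

    def test_single_member_identity(self, occurrence_table):
        model = fit("GLM", occurrence_table, ["sbt"])
        out = ensemble_predict([model], [1.0], occurrence_table)
        np.testing.assert_allclose(out, predict(model, occurrence_table))

    def test_two_member_hand_computation(self):
        a, b = _ConstantModel(1.0), _ConstantModel(0.0)
        out = _stub_predict([a, b], [0.9, 0.8], self.rows)
        np.testing.assert_allclose(out, 0.9 / 1.7)  # = 0.52941...
        # and through the package path
        out2 = np.average([1.0, 0.0], weights=[0.9 / 1.7, 0.8 / 1.7])
        assert out[0] == pytest.approx(out2)

    def test_consensus_preserved(self):
        members = [_ConstantModel(0.4), _ConstantModel(0.4)]
        out = _stub_predict(members, [0.9, 0.85], self.rows)
        np.testing.assert_allclose(out, 0.4)

    def test_weights_normalized_and_envelope_bound(self, occurrence_table):
        train, test = split(occurrence_table, seed=0)
        covs = ["sst", "sbt"]
        models = {a: fit(a, train, covs, seed=0) for a in ("GLM", "RF", "CTA")}
        reports = []
        from loligosdm import evaluate
        for a, m in models.items():
            reports.append(evaluate(m, test))
        ens = build_ensemble(models, reports, test, auc_min=0.5)
        assert ens.weights.sum() == pytest.approx(1.0)
        assert 0.0 <= ens.threshold <= 1.0
        preds = np.stack([predict(m, test) for m in ens.members])
        out = ens.predict(test)
        assert np.all(out >= preds.min(axis=0) - 1e-12)
        assert np.all(out <= preds.max(axis=0) + 1e-12)


class TestVariableImportance:
    def test_ignored_covariate_scores_zero(self, occurrence_table):
        # model fitted without sss cannot react to permuting it
        model = fit("GLM", occurrence_table, ["sbt"])

        class Wrapper:
            covariates = ["sbt", "sss"]

            def predict(self, rows):
                return predict(model, rows)

        imp = variable_importance(Wrapper(), occurrence_table, "sss", seed=0)
        assert imp == pytest.approx(0.0, abs=1e-12)

    def test_sole_driver_near_one(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({"x": rng.normal(size=400)})

        class Driver:
            covariates = ["x"]

            def predict(self, rows):
                return 1 / (1 + np.exp(-3 * rows["x"].to_numpy()))

        imp = variable_importance(Driver(), rows, "x", n_perm=30, seed=1)
        assert imp > 0.9

    def test_invariant_to_row_duplication(self, occurrence_table):
        model = fit("GLM", occurrence_table, ["sbt", "sbs"])
        rows = occurrence_table.iloc[:60]
        doubled = pd.concat([rows, rows], ignore_index=True)
        a = variable_importance(model, rows, "sbt", n_perm=20, seed=3)
        b = variable_importance(model, doubled, "sbt", n_perm=20, seed=3)
        assert a == pytest.approx(b, abs=0.1)

    def test_constant_predictions_score_zero(self):
        rows = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        model = _ConstantModel(0.7, covariates=("x",))
        assert variable_importance(model, rows, "x", seed=0) == 0.0

    def test_unknown_covariate_rejected(self, occurrence_table):
        model = fit("GLM", occurrence_table, ["sbt"])
        with pytest.raises(ValueError):
            variable_importance(model, occurrence_table, "chlorophyll")


class TestResponseCurve:
    def test_monotone_for_positive_linear_glm(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-2, 2, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-2 * x))).astype(int)
        tbl = pd.DataFrame({"presence": y, "x": x})
        model = fit("GLM", tbl, ["x"])
        curve = response_curve(model, tbl[["x"]], "x", grid=np.linspace(-2, 2, 30))
        assert np.all(np.diff(curve["suitability"]) >= -1e-9)

    def test_flat_model_flat_curve(self):
        rows = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        model = _ConstantModel(0.3, covariates=("x",))
        curve = response_curve(model, rows, "x")
        assert curve["suitability"].nunique() == 1

    def test_unknown_covariate_rejected(self, occurrence_table):
        model = fit("GLM", occurrence_table, ["sbt"])
        with pytest.raises(ValueError):
            response_curve(model, occurrence_table, "sss")

    def test_nonfocal_fixed_at_mean(self, occurrence_table):
        model = fit("GLM", occurrence_table, ["sbt", "sbs"])
        grid = np.array([18.0, 20.0, 22.0])
        curve = response_curve(model, occurrence_table, "sbt", grid=grid)
        strip = pd.DataFrame({
            "sbt": grid,
            "sbs": np.full(3, occurrence_table["sbs"].mean()),
        })
        np.testing.assert_allclose(
            curve["suitability"], predict(model, strip)
        )
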