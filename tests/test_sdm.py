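import numpy as np
import pandas as pd
import pytest

from rangeshift.metrics import EvalMetrics
from rangeshift.sdm import (ALGORITHMS, EnsembleMember, EnsembleModel,
                            TrainingSet, ensemble_predict, fit_algorithm,
                            gate_models, sample_pseudo_absences, split_cv)
from rangeshift.occurrences import OccurrenceSet
from rangeshift.predictors import PredictorStack

from conftest import make_grid


def metrics(tss, auc_):
    sens = (tss + 1) / 2
    return EvalMetrics(auc=auc_, tss=tss, sensitivity=sens, specificity=sens,
                       threshold=0.5)


def member(tss, auc_, algorithm="GLM"):
    return EnsembleMember(algorithm, 0, 0, None, metrics(tss, auc_))


def toy_trainingset(n_pres=20, n_abs=20, seed=0):
    rng = np.random.default_rng(seed)
    pres = pd.DataFrame({"x": rng.normal(2, 1, n_pres),
                         "y": rng.normal(0, 1, n_pres)})
    absn = pd.DataFrame({"x": rng.normal(-2, 1, n_abs),
                         "y": rng.normal(0, 1, n_abs)})
    return TrainingSet("sp", 0, pres, absn)


@pytest.fixture(scope="module")
def flat_stack():
    layers = {"a": make_grid(np.arange(3600.0).reshape(60, 60)),
              "b": make_grid(np.ones((60, 60)))}
    return PredictorStack("current", layers)


class TestPseudoAbsences:
    def occ(self, n, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"lon": rng.uniform(0.05, 5.9, n),
                           "lat": rng.uniform(-4.9, 0.9, n)})
        return OccurrenceSet("sp", df)

    def test_default_rule_small_sample_gets_1000(self, flat_stack):
        ts = sample_pseudo_absences(flat_stack, self.occ(500), 0, seed=1)
        assert len(ts.absence) == 1000

    def test_default_rule_matches_occurrences_when_large(self, flat_stack):
        ts = sample_pseudo_absences(flat_stack, self.occ(1200), 0, seed=1)
        assert len(ts.absence) == 1200

    def test_pa_cells_avoid_presence_cells(self, flat_stack):
        occ = self.occ(100, seed=3)
        ts = sample_pseudo_absences(flat_stack, occ, 0, seed=2, n_pa=500)
        g = flat_stack.grid
        pr, pc = g.cell_index(occ.records.lon, occ.records.lat)
        ar, ac = g.cell_index(*ts.absence_coords)
        presence_cells = set(zip(pr.tolist(), pc.tolist()))
        assert presence_cells.isdisjoint(zip(ar.tolist(), ac.tolist()))

    def test_deterministic_and_too_many_rejected(self, flat_stack):
        a = sample_pseudo_absences(flat_stack, self.occ(50), 0, seed=9)
        b = sample_pseudo_absences(flat_stack, self.occ(50), 0, seed=9)
        pd.testing.assert_frame_equal(a.absence, b.absence)
        with pytest.raises(ValueError, match="candidate cells"):
            sample_pseudo_absences(flat_stack, self.occ(50), 0, seed=1,
                                   n_pa=5000)


class TestSplit:
    def test_70_30_stratified_counts(self):
        ts = toy_trainingset(10, 10)
        tr, te = split_cv(ts, 0.7, 0, seed=4)
        assert len(tr.presence) == 7 and len(te.presence) == 3
        assert len(tr.absence) == 7 and len(te.absence) == 3

    def test_partition_property(self):
        ts = toy_trainingset(23, 31)
        tr, te = split_cv(ts, 0.7, 0, seed=5)
        got = pd.concat([tr.presence, te.presence]).sort_values("x")
        want = ts.presence.sort_values("x")
        assert np.allclose(got.to_numpy(), want.to_numpy())
        assert len(set(tr.presence.index) & set(te.presence.index)) == 0

    def test_deterministic(self):
        ts = toy_trainingset(30, 30)
        a = split_cv(ts, 0.7, 0, seed=6)[0]
        b = split_cv(ts, 0.7, 0, seed=6)[0]
        pd.testing.assert_frame_equal(a.presence, b.presence)


class TestAlgorithms:
    def test_sre_is_strict_envelope(self):
        pres = pd.DataFrame({"BIO1": [5.0, 10.0, 15.0]})
        absn = pd.DataFrame({"BIO1": [30.0]})
        model = fit_algorithm("SRE", TrainingSet("sp", 0, pres, absn))
        assert model.predict_score(np.array([[10.0]])) == 1.0
        assert model.predict_score(np.array([[20.0]])) == 0.0
        assert model.predict_score(np.array([[5.0]])) == 1.0  # boundary inside

    def test_glm_separable_perfect_auc(self):
        rng = np.random.default_rng(1)
        pres = pd.DataFrame({"x": rng.uniform(1, 2, 40),
                             "y": rng.normal(size=40)})
        absn = pd.DataFrame({"x": rng.uniform(-2, -1, 40),
                             "y": rng.normal(size=40)})
        ts = TrainingSet("sp", 0, pres, absn)
        model = fit_algorithm("GLM", ts)
        sp = model.predict_score(pres.to_numpy())
        sa = model.predict_score(absn.to_numpy())
        assert sp.min() > sa.max()

    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_scores_within_unit_interval(self, algo):
        ts = toy_trainingset(30, 30, seed=2)
        model = fit_algorithm(algo, ts, seed=3)
        X = np.random.default_rng(0).normal(0, 5, size=(200, 2))
        s = model.predict_score(X)
        assert np.all((s >= 0) & (s <= 1))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="roster"):
            fit_algorithm("MAXENT42", toy_trainingset())


class TestGating:
    def test_or_rule(self):
        ens = gate_models([member(0.65, 0.75), member(0.50, 0.85),
                           member(0.50, 0.70)], "sp", ["x"])
        flags = [m.included for m in ens.members]
        assert flags == [True, True, False]

    def test_weights_are_tss_normalised(self):
        ens = gate_models([member(0.8, 0.9), member(0.4, 0.9)], "sp", ["x"])
        w = [m.weight for m in ens.included]
        assert w == pytest.approx([2 / 3, 1 / 3])
        assert sum(w) == pytest.approx(1.0)
        excluded = gate_models([member(0.9, 0.9), member(0.1, 0.1)],
                               "sp", ["x"]).members[1]
        assert excluded.weight == 0.0

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError, match="ensemble empty"):
            gate_models([member(0.1, 0.5)], "sp", ["x"])

    def test_raising_gate_never_adds_members(self):
        rng = np.random.default_rng(11)
        members = [member(t, a) for t, a in rng.random((20, 2))]
        low = {id(m) for m in gate_models(members, "s", ["x"],
                                          tss_gate=0.3).included}
        high = {id(m) for m in gate_models(members, "s", ["x"],
                                           tss_gate=0.6).included}
        assert high <= low


class _ConstModel:
    def __init__(self, value):
        self.value = value

    def predict_score(self, X):
        return np.full(len(X), self.value)


class TestEnsemblePredict:
    @pytest.fixture
    def stack(self):
        return PredictorStack("current",
                              {"x": make_grid(np.random.default_rng(0)
                                              .random((5, 5)))})

    def ensemble(self, values_weights):
        members = []
        for v, w in values_weights:
            m = member(0.7, 0.9)
            m.model = _ConstModel(v)
            m.included, m.weight = True, w
            members.append(m)
        return EnsembleModel("sp", ["x"], members)

    def test_single_member_identity(self, stack):
        ens = self.ensemble([(0.3, 1.0)])
        out = ensemble_predict(ens, stack)
        assert np.allclose(out.grid.values, 0.3)

    def test_weighted_mean_of_constants(self, stack):
        ens = self.ensemble([(0.2, 0.5), (0.6, 0.5)])
        out = ensemble_predict(ens, stack)
        assert np.allclose(out.grid.values, 0.4)

    def test_convexity_bound(self, stack):
        ens = self.ensemble([(0.1, 0.25), (0.9, 0.75)])
        out = ensemble_predict(ens, stack)
        assert out.grid.values.min() >= 0.1 - 1e-12
        assert out.grid.values.max() <= 0.9 + 1e-12

    def test_missing_layer_named_in_error(self, stack):
        ens = self.ensemble([(0.5, 1.0)])
        ens.predictor_names = ["x", "BIO7"]
        with pytest.raises(ValueError, match="BIO7"):
            ensemble_predict(ens, stack)
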