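import numpy as np
import pytest

from alegpr import ensemble as ens
from alegpr import fermentation as fm
from alegpr import gmm
from alegpr.data import (
    LabeledSet,
    SplitSpec,
    UnlabeledPool,
    apply_standardizer,
    fit_standardizer,
    split_initial,
)
from alegpr.evaluation import alternating_split


@pytest.fixture(scope="module")
def labeled_training_block(default_dataset_module):
    train, _ = alternating_split(default_dataset_module)
    scaler = fit_standardizer(train)
    std = apply_standardizer(scaler, train)
    return LabeledSet(std.ids, std.X, std.y)


@pytest.fixture(scope="module")
def default_dataset_module():
    return fm.generate_dataset(fm.KineticParams(), seed=0)


class TestFitEnsemble:
    def test_single_component_equals_global(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.sin(X[:, 0])
        lab = LabeledSet(np.arange(30), X, y)
        e = ens.fit_ensemble(lab, K=1, seed=4)
        g = ens.fit_global(lab, seed=4)
        Xq = rng.normal(size=(15, 3))
        np.testing.assert_allclose(
            ens.predict_ensemble(e, Xq)[0], ens.predict_global(g, Xq), atol=1e-10
        )

    def test_components_align_with_phases(self, labeled_training_block):
        from sklearn.metrics import adjusted_rand_score

        model = ens.fit_ensemble(labeled_training_block, K=3, seed=0)
        labels = gmm.hard_assign(model.gmm, labeled_training_block.X)
        truth = fm.phase_labels(fm.KineticParams())[labeled_training_block.ids]
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 2))
        y = X[:, 0] ** 2
        lab = LabeledSet(np.arange(40), X, y)
        a = ens.fit_ensemble(lab, K=2, seed=7)
        b = ens.fit_ensemble(lab, K=2, seed=7)
        Xq = rng.normal(size=(9, 2))
        np.testing.assert_array_equal(
            ens.predict_ensemble(a, Xq)[0], ens.predict_ensemble(b, Xq)[0]
        )

    def test_small_components_are_merged(self, rng):
        # two tight blobs plus a stray point: K=3 must collapse to 2 usable experts
        X = np.vstack([
            rng.normal(0, 0.1, size=(10, 2)),
            rng.normal(8, 0.1, size=(10, 2)),
            [[4.0, 4.0]],
        ])
        y = np.concatenate([np.zeros(10), np.ones(10), [0.5]])
        lab = LabeledSet(np.arange(21), X, y)
        model = ens.fit_ensemble(lab, K=3, seed=1)
        assert len(model.local_models) <= 2 or all(
            m.X_train.shape[0] >= 3 for m in model.local_models.values()
        )


class TestPredictEnsemble:
    def test_weights_form_simplex(self, labeled_training_block, rng):
        model = ens.fit_ensemble(labeled_training_block, K=3, seed=0)
        Xq = rng.normal(size=(50, 7))
        _, trace = ens.predict_ensemble(model, Xq)
        np.testing.assert_allclose(trace["weights"].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(trace["weights"] >= 0)

    def test_weight_concentration_at_component_mean(self, rng):
        X = np.vstack([rng.normal(0, 0.5, size=(15, 2)), rng.normal(30, 0.5, size=(15, 2))])
        y = np.concatenate([X[:15, 0], 5 + X[15:, 1]])
        lab = LabeledSet(np.arange(30), X, y)
        model = ens.fit_ensemble(lab, K=2, seed=0)
        for k in model.local_models:
            xq = model.gmm.means[k][None]
            fused, trace = ens.predict_ensemble(model, xq)
            mu_local = trace["local_means"][0, trace["components"].index(k)]
            assert fused[0] == pytest.approx(mu_local, abs=1e-6)

    def test_fusion_equals_independent_weighted_sum(self, labeled_training_block, rng):
        """Fused output must equal sum_k y_qk * p(C_k|x_q) computed separately."""
        from alegpr import gpr

        model = ens.fit_ensemble(labeled_training_block, K=3, seed=0)
        Xq = rng.normal(size=(40, 7)) + labeled_training_block.X.mean(axis=0)
        fused, trace = ens.predict_ensemble(model, Xq)
        resp = gmm.responsibilities(model.gmm, Xq)
        oracle = np.zeros(len(Xq))
        for k, local in model.local_models.items():
            mu, _ = gpr.predict(local, Xq)
            weight = sum(
                resp[:, j]
                for j in range(model.gmm.K)
                if model.component_map[j] == k
            )
            oracle += weight * (mu * model.y_sd + model.y_mean)
        np.testing.assert_allclose(fused, oracle, atol=1e-12)


class TestFitVariant:
    def _problem(self, rng, n=60):
        # two separated operating regimes so the phase partition is unambiguous
        X = rng.normal(size=(n, 3))
        X[n // 2:, 0] += 12.0
        y = np.where(X[:, 0] > 6.0, X[:, 1], -X[:, 1])
        labeled = LabeledSet(np.arange(8), X[:8], y[:8])
        pool = UnlabeledPool(np.arange(8, n), X[8:])
        oracle = lambda ids: y[np.asarray(ids, dtype=int)]
        return labeled, pool, oracle

    def test_unknown_tag(self, rng):
        labeled, pool, oracle = self._problem(rng)
        with pytest.raises(ValueError, match="variant"):
            ens.fit_variant("XGPR", labeled, pool, oracle)

    @pytest.mark.parametrize("tag,model_type", [
        ("GPR", ens.GlobalModel),
        ("EGPR", ens.EnsembleModel),
        ("AL-GPR", ens.GlobalModel),
        ("AL-EGPR", ens.EnsembleModel),
    ])
    def test_composition(self, rng, tag, model_type):
        labeled, pool, oracle = self._problem(rng)
        run = ens.fit_variant(tag, labeled, pool, oracle, ns=10, n_iterations=2,
                              K=2, pruning_size=10, seed=0)
        assert isinstance(run.model, model_type)
        assert run.model.variant == tag
        assert run.labeled.n == 28 and run.pool.n == 32
        assert [h["n_labeled"] for h in run.history] == [8, 18, 28]

    def test_one_shot_exhaustion_equalizes_strategies(self, rng):
        labeled, pool, oracle = self._problem(rng)
        runs = {
            tag: ens.fit_variant(tag, labeled, pool, oracle, ns=pool.n,
                                 n_iterations=1, K=2, pruning_size=10, seed=3)
            for tag in ens.VARIANTS
        }
        sets = {tag: frozenset(r.labeled.ids.tolist()) for tag, r in runs.items()}
        assert len(set(sets.values())) == 1  # all variants labeled everything
        Xq = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            ens.predict_ensemble(runs["EGPR"].model, Xq)[0],
            ens.predict_ensemble(runs["AL-EGPR"].model, Xq)[0],
            atol=1e-10,
        )

    def test_early_stop(self, rng):
        labeled, pool, oracle = self._problem(rng)
        calls = []
        run = ens.fit_variant(
            "GPR", labeled, pool, oracle, ns=5, n_iterations=8, seed=0,
            per_iteration=lambda it, m, lab: calls.append(it),
            early_stop_rmse=np.inf, score=lambda m: 0.0,
        )
        assert calls == [0, 1]  # stopped right after the first refit


def test_bundle_roundtrip(tmp_path, rng):
    X = rng.normal(size=(30, 2))
    y = X[:, 0]
    lab = LabeledSet(np.arange(30), X, y)
    for model in (ens.fit_ensemble(lab, K=2, seed=0), ens.fit_global(lab, seed=0)):
        path = tmp_path / f"{model.variant}.json"
        ens.save_bundle(model, path)
        back = ens.load_bundle(path)
        Xq = rng.normal(size=(7, 2))
        np.testing.assert_allclose(
            ens.predict_variant(model, Xq), ens.predict_variant(back, Xq), atol=1e-12
        )
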