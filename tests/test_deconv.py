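"""Pseudo-bulk simulation, ensemble training contracts, and PCC evaluation."""

import numpy as np
import pytest

from histoimmune.deconv import (
    DeconvolutionEnsemble,
    make_pseudobulk,
    pcc_eval,
    predict_fractions,
    sample_fractions,
    simulate_pseudobulk_dataset,
    train_ensemble,
    PseudoBulkSample,
)
from histoimmune.synthetic_data import make_reference, simulate_cells


@pytest.fixture(scope="module")
def cells():
    ref = make_reference(4, 200, marker_frac=0.1, seed=1)
    return simulate_cells(ref, 150, ["b1"], seed=2)


class TestSampleFractions:
    def test_simplex_invariant(self):
        for seed in range(20):
            f = sample_fractions(5, alpha=0.7, seed=seed)
            assert abs(f.sum() - 1.0) < 1e-12 and np.all(f >= 0)

    def test_concentration_limit(self):
        f = sample_fractions(4, alpha=1e6, seed=0)
        np.testing.assert_allclose(f, 0.25, atol=2e-3)

    def test_dirichlet_moments(self):
        draws = np.stack([sample_fractions(3, alpha=1.0, seed=s) for s in range(10000)])
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / 10000)  # Var = a(1-a)/(a0+1), a0=3
        np.testing.assert_allclose(draws.mean(axis=0), 1 / 3, atol=3 * se)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            sample_fractions(3, alpha=0.0)


class TestMakePseudobulk:
    def test_one_hot_mixture_matches_type_profile(self, cells):
        f = np.array([0.0, 1.0, 0.0, 0.0])
        pb = make_pseudobulk(cells, f, n_cells=50, seed=3)
        np.testing.assert_allclose(pb.true_fractions, f)
        # expression is supported on the genes that type expresses
        assert np.all(np.isfinite(pb.expression)) and pb.expression.max() > 0

    def test_two_type_mixture_covers_both_marker_sets(self):
        ref = make_reference(2, 100, marker_frac=0.1, seed=4, fold_change=20)
        two = simulate_cells(ref, 100, ["b"], seed=5)
        pb = make_pseudobulk(two, np.array([0.5, 0.5]), n_cells=100, seed=6)
        for t in range(2):
            assert pb.expression[ref.marker_mask[t]].sum() > 0

    def test_realized_fractions_within_multinomial_error(self, cells):
        f = np.array([0.3, 0.7, 0.0, 0.0])
        reals = np.stack(
            [make_pseudobulk(cells, f, n_cells=100, seed=s).true_fractions for s in range(30)]
        )
        se = np.sqrt(0.3 * 0.7 / 100 / 30)
        assert abs(reals[:, 0].mean() - 0.3) < 4 * se

    def test_absent_type_errors_by_name(self, cells):
        with pytest.raises(ValueError, match="ghost"):
            make_pseudobulk(cells, np.array([0.5, 0.5]), n_cells=10, seed=0, cell_types=["type_0", "ghost"])

    def test_rejects_off_simplex_fractions(self, cells):
        with pytest.raises(ValueError):
            make_pseudobulk(cells, np.array([0.5, 0.2, 0.0, 0.0]), n_cells=10, seed=0)


@pytest.fixture(scope="module")
def tiny_fit(cells):
    X, F, cts = simulate_pseudobulk_dataset(cells, 300, n_cells=200, seed=7)
    est = DeconvolutionEnsemble(epochs=15, seed=0)
    est.fit(X[:250], F[:250], X_val=X[250:], y_val=F[250:])
    return est, X, F


class TestEnsemble:
    def test_predictions_on_simplex(self, tiny_fit):
        est, X, _ = tiny_fit
        pred = est.predict(X[:40])
        assert np.all(pred >= 0)
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-6)

    def test_three_distinct_members(self, tiny_fit):
        est, _, _ = tiny_fit
        assert len(est.members_) == 3
        depths = {len(m.layers) for m in est.members_}
        assert depths == {1, 2, 3}

    def test_better_than_uniform_on_training_samples(self, tiny_fit):
        est, X, F = tiny_fit
        pred = est.predict(X[:50])
        uniform = np.full_like(pred, 1 / pred.shape[1])
        l1_model = np.abs(pred - F[:50]).sum(axis=1)
        l1_unif = np.abs(uniform - F[:50]).sum(axis=1)
        assert l1_model.mean() < l1_unif.mean()

    def test_ensemble_not_worse_than_worst_member(self, tiny_fit):
        est, X, F = tiny_fit
        losses = est.validation_losses_(X[250:], F[250:])
        members, ensemble = losses[:-1], losses[-1]
        assert ensemble <= max(members)

    def test_determinism_same_seed(self, cells):
        X, F, _ = simulate_pseudobulk_dataset(cells, 60, n_cells=100, seed=8)
        p1 = DeconvolutionEnsemble(epochs=3, seed=5).fit(X, F).predict(X[:5])
        p2 = DeconvolutionEnsemble(epochs=3, seed=5).fit(X, F).predict(X[:5])
        np.testing.assert_array_equal(p1, p2)

    def test_gene_id_reconciliation_is_order_invariant(self, cells):
        import pandas as pd

        X, F, _ = simulate_pseudobulk_dataset(cells, 60, n_cells=100, seed=9)
        genes = list(cells.var_names)
        est = DeconvolutionEnsemble(epochs=3, seed=0, gene_ids=genes).fit(X, F)
        df = pd.DataFrame(X[:4], columns=genes)
        shuffled = df[df.columns[::-1]]
        np.testing.assert_allclose(est.predict(df), est.predict(shuffled), atol=1e-6)

    def test_low_gene_overlap_is_an_error(self, cells):
        import pandas as pd

        X, F, _ = simulate_pseudobulk_dataset(cells, 50, n_cells=100, seed=10)
        genes = list(cells.var_names)
        est = DeconvolutionEnsemble(epochs=2, seed=0, gene_ids=genes).fit(X, F)
        few = pd.DataFrame(X[:2, :40], columns=genes[:40])
        with pytest.raises(ValueError, match="50%"):
            est.predict(few)

    def test_missing_genes_imputed_with_warning(self, cells):
        import pandas as pd

        X, F, _ = simulate_pseudobulk_dataset(cells, 50, n_cells=100, seed=11)
        genes = list(cells.var_names)
        est = DeconvolutionEnsemble(epochs=2, seed=0, gene_ids=genes).fit(X, F)
        partial = pd.DataFrame(X[:2, :150], columns=genes[:150])
        with pytest.warns(UserWarning, match="missing"):
            pred = est.predict(partial)
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-6)

    def test_single_type_degenerate_target(self, cells):
        one_hot = np.zeros((40, 4))
        one_hot[:, 2] = 1.0
        X = np.stack(
            [
                make_pseudobulk(cells, one_hot[0], n_cells=60, seed=s).expression
                for s in range(40)
            ]
        )
        est = DeconvolutionEnsemble(epochs=20, seed=0).fit(X[:30], one_hot[:30])
        pred = est.predict(X[30:])
        assert np.all(pred.argmax(axis=1) == 2)
        assert pred[:, 2].mean() > 0.8

    def test_save_load_roundtrip(self, tiny_fit, tmp_path):
        est, X, _ = tiny_fit
        path = tmp_path / "deconv.npz"
        est.save(path)
        loaded = DeconvolutionEnsemble.load(path)
        np.testing.assert_allclose(loaded.predict(X[:6]), est.predict(X[:6]), atol=1e-7)

    def test_train_ensemble_wrapper_checks_dims(self, cells):
        s1 = PseudoBulkSample(np.zeros(10), np.array([0.5, 0.5]), 10)
        s2 = PseudoBulkSample(np.zeros(12), np.array([0.5, 0.5]), 10)
        with pytest.raises(ValueError):
            train_ensemble([s1], [s2])

    def test_wrapper_train_and_predict(self, cells):
        samples = [
            make_pseudobulk(cells, sample_fractions(4, seed=s), n_cells=80, seed=s)
            for s in range(50)
        ]
        ens = train_ensemble(samples[:40], samples[40:], {"epochs": 4, "seed": 1})
        pred = predict_fractions(ens, samples[0].expression)
        assert pred.shape == (1, 4)
        np.testing.assert_allclose(pred.sum(), 1.0, atol=1e-6)


class TestPccEval:
    def test_perfect_prediction(self):
        f = np.random.default_rng(0).dirichlet(np.ones(4), size=10)
        r = pcc_eval(f, f)
        np.testing.assert_allclose(r["per_sample"], 1.0)
        np.testing.assert_allclose(r["per_type"], 1.0)

    def test_affine_invariance(self):
        t = np.random.default_rng(1).dirichlet(np.ones(5), size=8)
        r = pcc_eval(2.0 * t + 0.1, t)
        np.testing.assert_allclose(r["per_sample"], 1.0, atol=1e-12)

    def test_uniform_prediction_flagged_undefined(self):
        t = np.random.default_rng(2).dirichlet(np.ones(4), size=6)
        p = np.full_like(t, 0.25)
        r = pcc_eval(p, t)
        assert np.all(np.isnan(r["per_sample"]))
        assert r["n_undefined"] >= 6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pcc_eval(np.zeros((2, 3)), np.zeros((3, 3)))
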