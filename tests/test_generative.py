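import numpy as np
import pandas as pd
import pytest

import cellshapes as cs
from cellshapes import generative
from cellshapes.generative import _forward_backward, _init_linear


class TestTraining:
    def test_loss_decreases(self, trained_model):
        _, history = trained_model
        assert history["mse"].iloc[-1] < history["mse"].iloc[0]

    def test_loss_is_weighted_sum_of_logged_parts(self, trained_model):
        model, history = trained_model
        beta = model.config.beta
        recomputed = (1 - beta) * history["mse"] + beta * history["kld"]
        assert np.abs(recomputed - history["loss"]).max() < 1e-8

    def test_seeded_determinism(self, table_200):
        cfg = cs.VAEConfig(epochs=40, seed=3)
        _, h1 = cs.train_vae(table_200, cfg)
        _, h2 = cs.train_vae(table_200, cfg)
        assert h1["loss"].iloc[-1] == h2["loss"].iloc[-1]

    def test_beta_zero_reduces_to_plain_autoencoder(self, table_200):
        _, history = cs.train_vae(table_200, cs.VAEConfig(epochs=5, seed=1,
                                                          beta=0.0))
        assert (history["loss"] == history["mse"]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cs.VAEConfig(beta=1.0)
        with pytest.raises(ValueError):
            cs.VAEConfig(epochs=0)

    def test_gradients_match_finite_differences(self):
        """Hand-derived backprop against central finite differences."""
        rng = np.random.default_rng(0)
        n, d, B = 6, 3, 5
        sizes = {"W1": (n, 2 * n), "W2": (2 * n, n), "Wm": (n, d),
                 "Wv": (n, d), "V1": (d, n), "V2": (n, 2 * n),
                 "V3": (2 * n, n)}
        params = {}
        for name, (fi, fo) in sizes.items():
            w, b = _init_linear(rng, fi, fo)
            params[name] = w
            params[("b" if name.startswith("W") else "c") + name[1:]] = b
        x = rng.normal(size=(B, n))
        eps = rng.normal(size=(B, d))
        beta = 0.3
        _, _, _, grads = _forward_backward(params, x, eps, beta)
        h = 1e-6
        for key in ("W1", "bm", "V3", "c1", "Wv"):
            flat = params[key].ravel()
            for idx in [0, flat.size // 2]:
                orig = flat[idx]
                flat[idx] = orig + h
                lp = _forward_backward(params, x, eps, beta)[0]
                flat[idx] = orig - h
                lm = _forward_backward(params, x, eps, beta)[0]
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert grads[key].ravel()[idx] == pytest.approx(fd, abs=1e-5)

    def test_model_save_load_round_trip(self, trained_model, tmp_path):
        model, _ = trained_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = generative.LatentModel.load(path)
        z = np.random.default_rng(0).standard_normal((4, 15))
        assert np.allclose(back.decode(z), model.decode(z))
        assert back.stats.columns == model.stats.columns


class TestGenerate:
    def test_onehot_valid_and_doa_clipped(self, trained_model):
        model, _ = trained_model
        gen = cs.generate(model, 200, seed=7)
        onehot = gen[model.onehot_columns].to_numpy()
        assert ((onehot == 0) | (onehot == 1)).all()
        assert (onehot.sum(axis=1) == 1).all()
        assert gen["doa"].between(0.0, 1.0).all()

    def test_same_seed_identical_batch(self, trained_model):
        model, _ = trained_model
        g1 = cs.generate(model, 25, seed=4)
        g2 = cs.generate(model, 25, seed=4)
        pd.testing.assert_frame_equal(g1, g2)

    def test_n_cells_validated(self, trained_model):
        with pytest.raises(ValueError):
            cs.generate(trained_model[0], 0)


class TestNaiveBaseline:
    def test_constant_feature_preserved(self):
        vecs = [np.array([4.0, float(i)]) for i in range(6)]
        t = cs.assemble_table(vecs, [0.5] * 6, ["a", "b"] * 3)
        gen = cs.naive_generate(t, 50, seed=1)
        assert (gen["f0"] == 4.0).all()

    def test_destroys_cross_feature_correlation(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=500)
        vecs = [np.array([a, 2 * a]) for a in u]  # perfectly correlated pair
        t = cs.assemble_table(vecs, rng.uniform(size=500), ["a", "b"] * 250)
        gen = cs.naive_generate(t, 500, seed=3)
        rho = np.corrcoef(gen["f0"], gen["f1"])[0, 1]
        assert abs(rho) < 0.2

    def test_marginals_preserved(self, table_200):
        from scipy.stats import ks_2samp

        gen = cs.naive_generate(table_200, 500, seed=5)
        for col in table_200.numeric_columns[:10] + ["doa"]:
            d = ks_2samp(table_200.frame[col], gen[col]).statistic
            assert d < 0.15


class TestFidelity:
    def test_real_vs_itself_zero_distance(self, table_200):
        _, stats = cs.normalize(table_200)
        fid = cs.fidelity_heatmaps(table_200.frame, table_200.frame,
                                   table_200.frame, stats.columns)
        assert fid["frobenius_to_real"]["vae"] == 0.0

    def test_matrices_symmetric_unit_diagonal(self, table_200, trained_model):
        model, _ = trained_model
        gen = cs.generate(model, 100, seed=2)
        naive = cs.naive_generate(table_200, 100, seed=2)
        _, stats = cs.normalize(table_200)
        fid = cs.fidelity_heatmaps(table_200.frame, gen, naive, stats.columns)
        for m in fid["matrices"].values():
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)

    def test_vae_reproduces_correlations_better_than_kde(self, table_200,
                                                         trained_model):
        """Coefficient covariation is the structure the VAE must capture."""
        model, _ = trained_model
        gen = cs.generate(model, 200, seed=7)
        naive = cs.naive_generate(table_200, 200, seed=7)
        _, stats = cs.normalize(table_200)
        fid = cs.fidelity_heatmaps(table_200.frame, gen, naive, stats.columns)
        assert (fid["frobenius_to_real"]["vae"]
                < fid["frobenius_to_real"]["naive"])


class TestNovelty:
    def test_training_row_has_zero_distance(self, table_200):
        _, stats = cs.normalize(table_200)
        copy = table_200.frame.iloc[[3]]
        out = cs.novelty_check(copy, table_200, stats)
        assert out["nearest_distance"].iloc[0] == 0.0
        assert out["nearest_real_id"].iloc[0] == table_200.frame.index[3]

    def test_generated_cells_are_novel(self, table_200, trained_model):
        model, _ = trained_model
        gen = cs.generate(model, 100, seed=9)
        _, stats = cs.normalize(table_200)
        out = cs.novelty_check(gen, table_200, stats)
        assert (out["nearest_distance"] > 0).all()

    def test_invariant_to_feature_order(self, table_200, trained_model):
        model, _ = trained_model
        gen = cs.generate(model, 20, seed=1)
        _, stats = cs.normalize(table_200)
        d1 = cs.novelty_check(gen, table_200, stats)["nearest_distance"]
        shuffled = gen[list(gen.columns[::-1])]
        d2 = cs.novelty_check(shuffled, table_200, stats)["nearest_distance"]
        assert np.allclose(d1.to_numpy(), d2.to_numpy())


def test_latent_manifold_samples_stay_in_training_range(table_200,
                                                        trained_model,
                                                        population_200):
    """Generated shapes must not extrapolate wildly in elongation.

    The training population lies on a low-dimensional manifold (elongation x
    protrusions); decoded samples should reconstruct to aspect ratios inside
    the training range with 20% margin for >= 95% of cells.
    """
    model, _ = trained_model
    gen = cs.generate(model, 100, seed=3)

    def aspect(points):
        ext = points.max(axis=0) - points.min(axis=0)
        return ext[0] / ext[1]

    train_aspects = []
    for b, _, _ in population_200:
        train_aspects.append(aspect(cs.align_boundary(b).points))
    lo, hi = min(train_aspects) / 1.2, max(train_aspects) * 1.2

    ok = 0
    for _, row in gen.iterrows():
        f = cs.FourierShape.from_flat(row.iloc[:62].to_numpy(dtype=float))
        rec = cs.reconstruct_fourier(f, 180)
        ok += lo <= aspect(rec.points) <= hi
    assert ok >= 95
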