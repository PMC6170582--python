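"""PCA and Gaussian-mixture clustering: oracles, EM properties, BIC
selection and the stepped component rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aepymorph.gmm import (
    FAMILIES,
    classify,
    fit_gmm,
    n_mixture_params,
    pca,
    select_model,
    stepped_pc_selection,
)


def frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"c{j}" for j in range(arr.shape[1])])


class TestPca:
    def test_collinear_points_explained_by_one_axis(self):
        t = np.linspace(-3, 3, 20)
        X = frame(np.column_stack([t, 2 * t]))
        res = pca(X)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_isotropic_cloud_splits_variance(self):
        rng = np.random.default_rng(0)
        X = frame(rng.normal(0, 1, size=(4000, 2)))
        res = pca(X)
        assert res.explained_fraction[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn_reference_up_to_sign(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(1)
        X = frame(rng.normal(10, 3, size=(5, 4)))
        ours = pca(X)
        ref = SkPCA(n_components=4).fit(X.to_numpy())
        for i in range(4):
            ref_load = ref.components_[i]
            our_load = ours.loadings.iloc[:, i].to_numpy()
            assert np.allclose(np.abs(our_load), np.abs(ref_load), atol=1e-8)
        assert np.allclose(
            ours.explained_fraction, ref.explained_variance_ratio_, atol=1e-8
        )

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        X = frame(rng.normal(0, 1, size=(30, 5)))
        res = pca(X)
        for i in range(res.n_components):
            col = res.loadings.iloc[:, i]
            assert col.iloc[col.abs().to_numpy().argmax()] > 0

    def test_missing_cells_rejected(self):
        X = frame([[1.0, 2.0], [np.nan, 3.0], [1.5, 2.5]])
        with pytest.raises(ValueError):
            pca(X)


class TestFitGmm:
    def test_two_tight_clusters_recovered(self):
        rng = np.random.default_rng(3)
        X = frame(
            np.concatenate([rng.normal(0, 0.1, 40), rng.normal(10, 0.1, 40)])[:, None]
        )
        for family in FAMILIES:
            model = fit_gmm(X, K=2, family=family, seed=0)
            means = sorted(model.means.ravel())
            assert means[0] == pytest.approx(0.0, abs=0.1)
            assert means[1] == pytest.approx(10.0, abs=0.1)
            asg = classify(model, X)
            assert (asg.uncertainty < 1e-6).all()

    def test_k1_matches_closed_form_mle(self):
        rng = np.random.default_rng(4)
        X = frame(rng.normal(5, 2, size=(60, 3)))
        model = fit_gmm(X, K=1, family="VVV", seed=0)
        arr = X.to_numpy()
        mu = arr.mean(axis=0)
        cov = (arr - mu).T @ (arr - mu) / len(arr)
        sign, logdet = np.linalg.slogdet(cov)
        d = 3
        closed = -0.5 * len(arr) * (d * np.log(2 * np.pi) + logdet + d)
        assert model.loglik == pytest.approx(closed, rel=1e-9)

    def test_eii_recovers_shared_spherical_variance(self):
        rng = np.random.default_rng(5)
        sigma = 1.5
        X = frame(
            np.vstack(
                [
                    rng.normal([0, 0], sigma, size=(250, 2)),
                    rng.normal([20, 20], sigma, size=(250, 2)),
                ]
            )
        )
        model = fit_gmm(X, K=2, family="EII", seed=0)
        assert model.covariances[0][0, 0] == pytest.approx(sigma**2, rel=0.1)

    def test_loglik_nondecreasing_over_iterations(self, tmt_clean):
        ds, _ = tmt_clean
        from aepymorph.impute import fit_scaling

        X = ds.matrix()
        scores = pca(fit_scaling(X).transform(X)).scores.iloc[:, :2]
        for family in ("EII", "VVV"):
            model = fit_gmm(scores, K=4, family=family, seed=1)
            trace = np.array(model.loglik_trace)
            assert (np.diff(trace) >= -1e-9 * (1 + np.abs(trace[:-1]))).all()

    def test_family_nesting_inequalities(self, tmt_clean):
        # maximum-likelihood nesting: the freer family can never fit worse
        ds, _ = tmt_clean
        from aepymorph.impute import fit_scaling

        X = ds.matrix()
        scores = pca(fit_scaling(X).transform(X)).scores.iloc[:, :3]
        lls = {
            fam: fit_gmm(scores, K=2, family=fam, seed=2, n_restarts=5).loglik
            for fam in ("EII", "EEE", "VVV")
        }
        assert lls["VVV"] >= lls["EEE"] - 1e-6
        assert lls["EEE"] >= lls["EII"] - 1e-6

    def test_beats_every_hard_partition(self):
        # brute-force oracle: 8 points in 1-D, K=2 - the EM mixture loglik
        # must reach at least the best of all hard two-part Gaussian fits
        pts = np.array([0.0, 0.3, 0.5, 0.9, 4.8, 5.1, 5.4, 5.9])
        X = frame(pts[:, None])
        best_hard = -np.inf
        for bits in itertools.product([0, 1], repeat=8):
            idx = np.array(bits, dtype=bool)
            if idx.sum() < 2 or (~idx).sum() < 2:
                continue
            ll = 0.0
            ok = True
            for part in (pts[idx], pts[~idx]):
                mu, var = part.mean(), part.var()
                if var <= 1e-12:
                    ok = False
                    break
                w = len(part) / len(pts)
                ll += np.sum(
                    np.log(w)
                    - 0.5 * (np.log(2 * np.pi * var) + (part - mu) ** 2 / var)
                )
            if ok:
                best_hard = max(best_hard, ll)
        model = fit_gmm(X, K=2, family="VVV", seed=0, n_restarts=6)
        assert model.loglik >= best_hard - 1e-6

    def test_comparable_to_sklearn_reference(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal([0, 0], 1, size=(60, 2)), rng.normal([6, 3], 1, size=(60, 2))]
        )
        ours = fit_gmm(frame(X), K=2, family="VVV", seed=0, n_restarts=5)
        ref = GaussianMixture(
            n_components=2, covariance_type="full", n_init=5, random_state=0,
            reg_covar=0,
        ).fit(X)
        ref_ll = ref.score(X) * len(X)
        assert ours.loglik == pytest.approx(ref_ll, rel=1e-4)

    def test_n_params_accounting(self):
        assert n_mixture_params("EII", K=3, d=2) == 2 + 6 + 1
        assert n_mixture_params("VVV", K=2, d=3) == 1 + 6 + 2 * 6
        assert n_mixture_params("EEE", K=4, d=2) == 3 + 8 + 3

    def test_needs_more_points_than_components(self):
        X = frame(np.arange(3, dtype=float)[:, None])
        with pytest.raises(ValueError):
            fit_gmm(X, K=3, family="EII")


class TestClassify:
    def test_equidistant_point_has_half_uncertainty(self):
        rng = np.random.default_rng(7)
        X = frame(
            np.concatenate([rng.normal(-5, 1, 50), rng.normal(5, 1, 50)])[:, None]
        )
        model = fit_gmm(X, K=2, family="EII", seed=0)
        # symmetrise the fitted model exactly, then probe the midpoint
        m = abs(model.means.ravel()).mean()
        model.means = np.array([[-m], [m]])
        model.weights = np.array([0.5, 0.5])
        cov = model.covariances.mean(axis=0)
        model.covariances = np.array([cov, cov])
        asg = classify(model, frame([[0.0]]))
        assert asg.uncertainty.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_responsibilities_sum_to_one(self, tmt_clean):
        ds, _ = tmt_clean
        from aepymorph.impute import fit_scaling

        X = ds.matrix()
        scores = pca(fit_scaling(X).transform(X)).scores.iloc[:, :2]
        model = fit_gmm(scores, K=4, family="VVI", seed=0)
        asg = classify(model, scores)
        assert np.allclose(asg.responsibilities.sum(axis=1), 1.0)
        assert ((asg.uncertainty >= 0) & (asg.uncertainty <= 1 - 1 / 4)).all()

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        X = frame(rng.normal(0, 1, size=(30, 2)))
        model = fit_gmm(X, K=2, family="EII", seed=0)
        with pytest.raises(ValueError):
            classify(model, frame(rng.normal(0, 1, size=(5, 3))))


class TestModelSelection:
    def test_single_cloud_selects_one_component(self):
        rng = np.random.default_rng(9)
        X = frame(rng.normal(0, 1, size=(120, 2)))
        sel = select_model(X, K_range=range(1, 5), seed=0)
        assert sel.model.K == 1

    def test_well_separated_four_clusters(self, tmt_clean):
        ds, _ = tmt_clean
        from aepymorph.impute import fit_scaling

        X = ds.matrix()
        scores = pca(fit_scaling(X).transform(X)).scores.iloc[:, :2]
        sel = select_model(scores, K_range=range(1, 7), seed=0)
        assert sel.model.K == 4
        assert sel.stable
        assert sel.margin > 2.0

    def test_bic_table_shape(self, tmt_clean):
        ds, _ = tmt_clean
        from aepymorph.impute import fit_scaling

        X = ds.matrix()
        scores = pca(fit_scaling(X).transform(X)).scores.iloc[:, :1]
        sel = select_model(scores, K_range=[1, 2], families=("EII", "VVV"), seed=0)
        assert sel.bic_table.shape == (2, 2)


class TestSteppedSelection:
    def test_structure_on_second_component_needs_two_steps(self):
        # PC1 is pure high-variance noise; the clusters separate only on PC2
        rng = np.random.default_rng(10)
        n = 60
        noise_axis = rng.normal(0, 12, size=2 * n)
        group_axis = np.concatenate([rng.normal(-3, 1, n), rng.normal(3, 1, n)])
        res = pca(frame(np.column_stack([noise_axis, group_axis])))
        stepped = stepped_pc_selection(res, K_range=range(1, 4), seed=0)
        assert stepped.n_pcs_used == 2
        assert stepped.model.K == 2
        assert stepped.stable

    def test_structure_on_first_component_needs_one_step(self, tmt_clean):
        ds, _ = tmt_clean
        from aepymorph.impute import fit_scaling

        X = ds.matrix()
        res = pca(fit_scaling(X).transform(X))
        stepped = stepped_pc_selection(res, K_range=range(1, 7), seed=0)
        assert stepped.n_pcs_used == 1
        assert stepped.model.K == 4

    def test_structureless_data_flagged_unstable(self):
        rng = np.random.default_rng(11)
        res = pca(frame(rng.normal(0, 1, size=(80, 3))))
        stepped = stepped_pc_selection(res, K_range=range(1, 4), seed=0, max_pcs=2)
        assert not stepped.stable
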