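"""Principal-curve fitting, pseudotime assignment and ordering tests."""

import numpy as np
import pandas as pd
import pytest

from cafpaths.cluster import embed_pca
from cafpaths.stats import spearman_rho
from cafpaths.syndata import expected_log_means, simulate_dataset
from cafpaths.trajectory import (
    PrincipalCurve,
    TrajectoryResult,
    assign_pseudotime,
    fit_principal_curve,
)
from cafpaths.trajectory import test_ordering as ordering_test

from conftest import small_sim_config


def _line_points(n=30, d=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    direction = np.array([2.0, -1.0, 0.5][:d])
    X = t[:, None] * direction[None, :]
    if noise:
        X = X + noise * rng.normal(size=X.shape)
    return X, t


class TestPrincipalCurve:
    def test_line_is_a_fixed_point(self):
        X, t = _line_points()
        pc = fit_principal_curve(X)
        assert pc.mean_sq_dist_ == pytest.approx(0.0, abs=1e-10)
        lam = pc.transform(X)
        norm = (lam - lam.min()) / (lam.max() - lam.min())
        ordered = norm if norm[0] < norm[-1] else 1 - norm
        np.testing.assert_allclose(ordered, t, atol=1e-8)

    def test_beats_straight_line_on_quadratic_arc(self):
        t = np.linspace(-1, 1, 60)
        X = np.column_stack([t, t ** 2])
        pc = fit_principal_curve(X, smooth_span=0.25)
        # PC1 oracle: best straight line through the centred data
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        resid = Xc - np.outer(Xc @ vt[0], vt[0])
        msd_line = float((resid ** 2).sum(axis=1).mean())
        assert pc.mean_sq_dist_ < msd_line

    def test_deterministic_given_inputs(self):
        X, _ = _line_points(noise=0.05, seed=4)
        pc1 = fit_principal_curve(X)
        pc2 = fit_principal_curve(X)
        np.testing.assert_array_equal(pc1.curve_points_, pc2.curve_points_)
        np.testing.assert_array_equal(pc1.lambda_, pc2.lambda_)

    def test_pseudotime_invariant_under_rotation(self):
        X, _ = _line_points(n=40, noise=0.05, seed=5)
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        lam1 = fit_principal_curve(X).lambda_
        lam2 = fit_principal_curve(X @ Q.T).lambda_
        np.testing.assert_allclose(lam1, lam2, atol=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_principal_curve(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="2 dimensions"):
            fit_principal_curve(np.ones((20, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            fit_principal_curve(np.ones((20, 3)))


class TestAssignPseudotime:
    def _result(self, root="root"):
        X, t = _line_points(n=20)
        emb = pd.DataFrame(X, index=[f"c{i}" for i in range(len(X))])
        labels = pd.Series(np.where(t < 0.5, "root", "tip"), index=emb.index)
        pc = fit_principal_curve(X)
        return assign_pseudotime(pc, emb, labels, root), t

    def test_root_population_sits_at_low_end(self):
        res, t = self._result()
        root_med = res.pseudotime[(res.labels == "root").to_numpy()].median()
        tip_med = res.pseudotime[(res.labels == "tip").to_numpy()].median()
        assert root_med < tip_med
        assert res.pseudotime.min() == 0.0
        assert res.pseudotime.max() == 1.0

    def test_axis_reversal_leaves_pseudotime_unchanged(self):
        X, t = _line_points(n=20)
        emb = pd.DataFrame(X, index=[f"c{i}" for i in range(len(X))])
        labels = pd.Series(np.where(t < 0.5, "root", "tip"), index=emb.index)
        res1 = assign_pseudotime(fit_principal_curve(X), emb, labels, "root")
        flipped = pd.DataFrame(-X, index=emb.index)
        res2 = assign_pseudotime(fit_principal_curve(-X), flipped, labels,
                                 "root")
        np.testing.assert_allclose(res1.pseudotime, res2.pseudotime, atol=1e-8)

    def test_missing_root_is_an_error(self):
        X, t = _line_points(n=20)
        emb = pd.DataFrame(X, index=[f"c{i}" for i in range(len(X))])
        labels = pd.Series("tip", index=emb.index)
        with pytest.raises(ValueError, match="absent"):
            assign_pseudotime(fit_principal_curve(X), emb, labels, "root")


class TestNoiselessRecovery:
    def test_rank_order_exact_in_deterministic_limit(self):
        cfg = small_sim_config(seed=5, continuum_noise_sd=0.0)
        _, truth = simulate_dataset(cfg)
        cont = truth["latent_pseudotime"].notna()
        log_mu, _ = expected_log_means(cfg, truth[cont])
        emb = embed_pca(log_mu, n_pc=10)
        coords = pd.DataFrame(emb.coords, index=truth.index[cont])
        labels = truth.loc[cont, "fib_subtype"].replace({"tr_MSCF": "tr-MSCF"})
        res = assign_pseudotime(fit_principal_curve(coords.to_numpy()),
                                coords, labels, "tr-MSCF")
        t_true = truth.loc[cont, "latent_pseudotime"].to_numpy()
        assert np.array_equal(np.argsort(np.argsort(res.pseudotime.to_numpy())),
                              np.argsort(np.argsort(t_true)))
        assert spearman_rho(res.pseudotime.to_numpy(), t_true) >= 1.0 - 1e-9


class TestOrdering:
    def _make_result(self, t_a, t_b):
        n = len(t_a) + len(t_b)
        index = pd.Index([f"c{i}" for i in range(n)])
        pt = pd.Series(np.concatenate([t_a, t_b]), index=index)
        labels = pd.Series(["A"] * len(t_a) + ["B"] * len(t_b), index=index)
        return TrajectoryResult(pseudotime=pt, labels=labels,
                                curve_points=np.zeros((2, 2)),
                                root_population="A",
                                embedding=pd.DataFrame(index=index))

    def test_separated_labels_are_significant_with_direction(self):
        rng = np.random.default_rng(0)
        res = self._make_result(rng.uniform(0.0, 0.4, 12),
                                rng.uniform(0.6, 1.0, 12))
        stat, p, direction = ordering_test(res, "B", "A")
        assert direction == "B"
        assert p < 0.05
        assert len(res.ordering_tests) == 1

    def test_identical_distributions_tie(self):
        vals = np.linspace(0, 1, 10)
        res = self._make_result(vals, vals)
        _, p, direction = ordering_test(res, "A", "B")
        assert p > 0.9
        assert direction == "tie"

    def test_small_or_missing_labels_rejected(self):
        res = self._make_result([0.1, 0.2], [0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="fewer than 3"):
            ordering_test(res, "A", "B")
        res3 = self._make_result([0.1, 0.2, 0.3], [0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="no cells"):
            ordering_test(res3, "A", "C")

    def test_default_synthetic_ordering(self, default_report):
        """myCAF later than iCAF, iCAF later than tr-MSCF, both significant."""
        tests = pd.DataFrame(default_report.ordering_tests)
        my_icaf = tests[(tests["later"] == "myCAF")
                        & (tests["earlier"] == "iCAF")]
        assert len(my_icaf) == 1
        assert my_icaf["p_value"].iloc[0] < 0.05
        icaf_mscf = tests[(tests["later"] == "iCAF")
                          & (tests["earlier"] == "tr-MSCF")]
        assert len(icaf_mscf) == 1
        assert icaf_mscf["p_value"].iloc[0] < 0.05
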