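"""Growth-parameter extraction and strain-panel decomposition tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bactaging import (GrowthCurve, decompose_and_cluster,
                       extract_growth_params, log_transform, panel_matrix)


def make_curve(times, od, strain="s", medium="m"):
    return GrowthCurve(strain=strain, medium=medium, times=np.asarray(times),
                       od=np.asarray(od))


class TestLogTransform:
    def test_constant_series_is_zero(self):
        c = make_curve(np.arange(12.0), np.full(12, 0.3))
        assert np.allclose(log_transform(c), 0.0)

    def test_exponential_gives_straight_line(self):
        t = np.linspace(0, 4, 40)
        c = make_curve(t, 0.01 * np.exp(1.5 * t))
        y = log_transform(c)
        slope = np.polyfit(t, y, 1)[0]
        assert slope == pytest.approx(1.5, rel=1e-6)

    def test_doubling_steps_are_ln2(self):
        od = 0.01 * 2.0 ** np.arange(12)
        c = make_curve(np.arange(12.0), od)
        assert np.allclose(np.diff(log_transform(c)), np.log(2))


class TestExtractGrowthParams:
    def test_pure_exponential(self):
        t = np.arange(0, 5, 0.05)
        r = np.log(2) / 0.5  # 30-min doubling
        p = extract_growth_params(make_curve(t, 0.01 * np.exp(r * t)))
        assert p.mgr == pytest.approx(r, abs=1e-6)
        assert p.texp == pytest.approx(t[-1] - t[0], abs=1e-9)

    def test_noiseless_logistic_spg_and_auc(self):
        r, K, N0 = 1.0, 1.0, 0.01
        t = np.arange(0, 15, 0.005)
        od = K / (1 + (K / N0 - 1) * np.exp(-r * np.clip(t - 1.0, 0, None)))
        p = extract_growth_params(make_curve(t, od))
        assert p.spg == pytest.approx(np.log(100), abs=0.01)
        tf = np.linspace(0, t[-1], 400_001)
        nf = K / (1 + (K / N0 - 1) * np.exp(-r * np.clip(tf - 1.0, 0, None)))
        auc_oracle = np.trapezoid(np.log(nf / N0), tf)
        assert p.auc == pytest.approx(auc_oracle, rel=0.01)

    def test_flat_curve_all_zero(self):
        p = extract_growth_params(make_curve(np.arange(20.0),
                                             np.full(20, 0.25)))
        assert (p.mgr, p.spg, p.auc, p.texp) == (0.0, 0.0, 0.0, 0.0)

    def test_mgr_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 10, 60)
        od = 0.01 * np.exp(0.8 * t) + rng.normal(0, 1e-4, t.size)
        od = np.clip(od, 1e-3, None)
        p1 = extract_growth_params(make_curve(t, od))
        p2 = extract_growth_params(make_curve(t, 5.0 * od))
        assert p2.mgr == pytest.approx(p1.mgr, rel=1e-9)

    def test_auc_split_additivity(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 8, 41)
        od = np.clip(0.01 * np.exp(0.5 * t) * np.exp(rng.normal(0, 0.05, t.size)),
                     1e-3, None)
        c = make_curve(t, od)
        p = extract_growth_params(c)
        y = log_transform(c)
        k = 20
        assert p.auc == pytest.approx(
            np.trapezoid(y[:k + 1], t[:k + 1]) + np.trapezoid(y[k:], t[k:]),
            abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            extract_growth_params(make_curve(np.arange(5.0), np.ones(5)))
        with pytest.raises(ValueError):
            extract_growth_params(make_curve(np.arange(20.0), np.ones(20)),
                                  window=15)


def _params_table(strains, media, rng):
    rows = []
    for s in strains:
        for m in media:
            rows.append({"strain": s, "medium": m,
                         "mgr": rng.normal(1, 0.1), "spg": rng.normal(4, 0.3),
                         "auc": rng.normal(20, 2), "texp": rng.normal(3, 0.2)})
    return pd.DataFrame(rows)


class TestPanelMatrix:
    def test_single_strain_rejected(self):
        df = _params_table(["a"], ["LB"], np.random.default_rng(0))
        with pytest.raises(ValueError):
            panel_matrix(df)

    def test_two_identical_strains_center_to_zero(self):
        rng = np.random.default_rng(1)
        df = _params_table(["a"], ["LB", "M9G"], rng)
        df2 = df.copy()
        df2["strain"] = "b"
        z, _ = panel_matrix(pd.concat([df, df2], ignore_index=True))
        assert np.allclose(z.to_numpy(), 0.0)

    def test_missing_cell_is_an_error(self):
        df = _params_table(["a", "b"], ["LB", "M9G"],
                           np.random.default_rng(2))
        with pytest.raises(ValueError, match="missing"):
            panel_matrix(df.iloc[:-1])

    def test_duplicated_feature_correlates_fully(self):
        df = _params_table(["a", "b", "c"], ["LB"], np.random.default_rng(5))
        df["spg"] = df["mgr"]
        _, corr = panel_matrix(df)
        assert corr.loc["mgr-LB", "spg-LB"] == pytest.approx(1.0)


class TestDecomposeAndCluster:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(np.outer(rng.normal(size=20), rng.normal(size=8)))
        dec = decompose_and_cluster(M, n_clusters=2)
        assert dec.variance_explained[0] >= 0.999

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (15, 6)), rng.normal(10, 1, (15, 6))])
        dec = decompose_and_cluster(pd.DataFrame(X), n_clusters=2)
        truth = np.repeat([0, 1], 15)
        assert adjusted_rand_score(truth, dec.cluster_labels.to_numpy()) == 1.0

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 5))
        dec = decompose_and_cluster(pd.DataFrame(X), n_clusters=2)
        assert np.abs(dec.reconstruct() - X).max() < 1e-8

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 6))
        dec = decompose_and_cluster(pd.DataFrame(X), n_clusters=2)
        L = dec.loadings.to_numpy()
        assert np.abs(L.T @ L - np.eye(L.shape[1])).max() < 1e-8

    def test_cluster_invariant_to_strain_order(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(8, 1, (10, 4))])
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(20)])
        perm = rng.permutation(20)
        d1 = decompose_and_cluster(df, n_clusters=2)
        d2 = decompose_and_cluster(df.iloc[perm], n_clusters=2)
        aligned = d2.cluster_labels.reindex(df.index)
        assert adjusted_rand_score(d1.cluster_labels, aligned) == 1.0

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 12))
        dec = decompose_and_cluster(pd.DataFrame(X), n_clusters=2)
        assert dec.variance_explained[0] < 0.35

    def test_too_many_clusters(self):
        X = pd.DataFrame(np.random.default_rng(5).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            decompose_and_cluster(X, n_clusters=10)
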