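import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dynfc.nbs import (
    DesignSpec,
    build_design,
    cohens_f2,
    edgewise_glm,
    permutation_fwe,
    subnetwork_report,
    supra_components,
    threshold_sweep,
)


def make_networks(rng, n_subj, n_nodes):
    nets = rng.standard_normal((n_subj, n_nodes, n_nodes))
    nets = (nets + nets.transpose(0, 2, 1)) / 2
    for net in nets:
        np.fill_diagonal(net, 0.0)
    return nets


def make_pheno(rng, n, group=True):
    df = pd.DataFrame(
        {
            "participant_id": [f"sub-{i}" for i in range(n)],
            "age": rng.uniform(18, 35, n),
            "mean_fd": rng.uniform(0.05, 0.2, n),
            "score": rng.standard_normal(n),
        }
    )
    if group:
        df["group"] = np.where(np.arange(n) % 2 == 0, "HC", "CHR")
    return df


class TestDesign:
    def test_duplicate_variables_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            DesignSpec(contrast="age", covariates=("age",))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            DesignSpec(contrast="age", kind="anova")

    def test_collinear_design_names_columns(self, rng):
        pheno = make_pheno(rng, 10)
        pheno["age2"] = 2 * pheno["age"]
        with pytest.raises(ValueError, match="collinear"):
            build_design(pheno, DesignSpec(contrast="score",
                                           covariates=("age", "age2")))

    def test_constant_covariate_dropped_with_warning(self, rng):
        pheno = make_pheno(rng, 10)
        pheno["flag"] = 0
        with pytest.warns(UserWarning, match="constant"):
            X, Z = build_design(pheno, DesignSpec(contrast="score",
                                                  covariates=("flag", "age")))
        assert X.shape[1] == 3  # intercept, score, age

    def test_two_level_factor_encoded(self, rng):
        pheno = make_pheno(rng, 10)
        X, _ = build_design(pheno, DesignSpec(contrast="group", kind="ancova"))
        assert set(np.unique(X[:, 1])) == {0.0, 1.0}


class TestEdgewiseGlm:
    def test_f_equals_squared_t_for_binary_contrast(self, rng):
        # classical identity: with a binary predictor and no covariates,
        # the partial F equals the squared equal-variance two-sample t
        nets = make_networks(rng, 16, 6)
        pheno = make_pheno(rng, 16)
        es = edgewise_glm(nets, pheno, DesignSpec(contrast="group",
                                                  kind="ancova"))
        grp = (pheno["group"] == "HC").to_numpy()
        iu = np.triu_indices(6, 1)
        for i, j in zip(*iu):
            edge = nets[:, i, j]
            t_stat, _ = sps.ttest_ind(edge[grp], edge[~grp], equal_var=True)
            assert es.f[i, j] == pytest.approx(t_stat**2, abs=1e-8)

    def test_matches_bruteforce_normal_equations(self, rng):
        nets = make_networks(rng, 20, 5)
        pheno = make_pheno(rng, 20)
        design = DesignSpec(contrast="score", covariates=("age", "mean_fd"))
        es = edgewise_glm(nets, pheno, design)
        X = np.column_stack([np.ones(20), pheno["score"], pheno["age"],
                             pheno["mean_fd"]])
        Z = X[:, [0, 2, 3]]
        iu = np.triu_indices(5, 1)
        for i, j in zip(*iu):
            y = nets[:, i, j]
            bf = np.linalg.lstsq(X, y, rcond=None)[0]
            rss_f = np.sum((y - X @ bf) ** 2)
            bz = np.linalg.lstsq(Z, y, rcond=None)[0]
            rss_r = np.sum((y - Z @ bz) ** 2)
            f_oracle = (rss_r - rss_f) / (rss_f / (20 - 4))
            assert es.f[i, j] == pytest.approx(f_oracle, abs=1e-10)
            assert np.sign(es.t[i, j]) == np.sign(bf[1])

    def test_null_false_positive_rate(self, rng):
        # response permuted randomly: ~5% of edges significant at p<.05
        nets = make_networks(rng, 40, 20)
        rates = []
        for rep in range(10):
            pheno = make_pheno(np.random.default_rng(rep), 40)
            es = edgewise_glm(nets, pheno, DesignSpec(contrast="score"))
            iu = np.triu_indices(20, 1)
            p = sps.f.sf(es.f[iu], 1, 40 - 2)
            rates.append((p < 0.05).mean())
        assert 0.02 < np.mean(rates) < 0.08

    def test_constant_edge_zero_f(self, rng):
        nets = make_networks(rng, 12, 4)
        nets[:, 0, 1] = nets[:, 1, 0] = 3.0
        pheno = make_pheno(rng, 12)
        es = edgewise_glm(nets, pheno, DesignSpec(contrast="score"))
        assert es.f[0, 1] == 0.0


class TestSupraComponents:
    def test_chain_is_one_component(self):
        f = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            f[i, j] = f[j, i] = 10.0
        comps = supra_components(f, 5.0)
        assert len(comps) == 1
        assert comps[0]["extent"] == 3

    def test_disjoint_edges_two_components(self):
        f = np.zeros((4, 4))
        f[0, 1] = f[1, 0] = 10.0
        f[2, 3] = f[3, 2] = 10.0
        comps = supra_components(f, 5.0)
        assert [c["extent"] for c in comps] == [1, 1]

    def test_nothing_supra_threshold(self):
        assert supra_components(np.zeros((4, 4)), 5.0) == []

    def test_threshold_nestedness(self, rng):
        f = np.abs(make_networks(rng, 1, 10)[0]) * 10
        prev = None
        for thr in [2.0, 4.0, 6.0, 8.0]:
            comps = supra_components(f, thr)
            max_ext = max((c["extent"] for c in comps), default=0)
            if prev is not None:
                assert max_ext <= prev
            prev = max_ext


class TestPermutationFwe:
    def test_determinism(self, rng):
        nets = make_networks(rng, 15, 6)
        pheno = make_pheno(rng, 15)
        design = DesignSpec(contrast="score", covariates=("age",))
        a = permutation_fwe(nets, pheno, design, threshold=4.0, n_perm=200,
                            seed=9)
        b = permutation_fwe(nets, pheno, design, threshold=4.0, n_perm=200,
                            seed=9)
        assert [c.fwe_p for c in a.components] == [c.fwe_p for c in b.components]

    def test_low_perm_warns(self, rng):
        nets = make_networks(rng, 15, 5)
        pheno = make_pheno(rng, 15)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_fwe(nets, pheno, DesignSpec(contrast="score"),
                            threshold=4.0, n_perm=50, seed=0)

    def test_fwe_p_monotone_in_extent(self, rng):
        nets = make_networks(rng, 20, 12)
        pheno = make_pheno(rng, 20)
        res = permutation_fwe(nets, pheno, DesignSpec(contrast="score"),
                              threshold=2.0, n_perm=200, seed=1)
        extents = [c.extent for c in res.components]
        ps = [c.fwe_p for c in res.components]
        for (e1, p1) in zip(extents, ps):
            for (e2, p2) in zip(extents, ps):
                if e1 > e2:
                    assert p1 <= p2

    def test_p_never_zero(self, rng):
        nets = make_networks(rng, 15, 6)
        pheno = make_pheno(rng, 15)
        res = permutation_fwe(nets, pheno, DesignSpec(contrast="score"),
                              threshold=1.0, n_perm=150, seed=2)
        for c in res.components:
            assert c.fwe_p >= 1 / 151


class TestThresholdSweep:
    def test_one_result_per_threshold(self, rng):
        nets = make_networks(rng, 15, 6)
        pheno = make_pheno(rng, 15)
        sweep = threshold_sweep(nets, pheno, DesignSpec(contrast="score"),
                                thresholds=[6.0, 19.0, 28.0], n_perm=100,
                                seed=0)
        assert [r.threshold for r in sweep] == [6.0, 19.0, 28.0]

    def test_all_empty_above_max_f(self, rng):
        nets = make_networks(rng, 15, 6)
        pheno = make_pheno(rng, 15)
        es = edgewise_glm(nets, pheno, DesignSpec(contrast="score"))
        fmax = es.f.max()
        sweep = threshold_sweep(nets, pheno, DesignSpec(contrast="score"),
                                thresholds=[fmax + 1, fmax + 2], n_perm=100,
                                seed=0)
        assert all(r.components == [] for r in sweep)

    def test_non_ascending_rejected(self, rng):
        nets = make_networks(rng, 15, 6)
        pheno = make_pheno(rng, 15)
        with pytest.raises(ValueError, match="ascending"):
            threshold_sweep(nets, pheno, DesignSpec(contrast="score"),
                            thresholds=[6.0, 6.0], n_perm=100, seed=0)


class TestCohensF2:
    def test_arithmetic_identity(self):
        # direct check of f2 = (R2f - R2r) / (1 - R2f) on crafted data:
        # R2_full = 0.5, R2_reduced = 0.25 -> f2 = 0.5
        r2f, r2r = 0.5, 0.25
        assert (r2f - r2r) / (1 - r2f) == pytest.approx(0.5)

    def test_null_contrast_small_mean_f2(self, rng):
        nets = make_networks(rng, 40, 12)
        pheno = make_pheno(rng, 40)
        out = cohens_f2(nets, pheno, DesignSpec(contrast="score",
                                                covariates=("age",)))
        assert out["mean"] < 0.15  # E[f2] ~ 1/(n-p) under the null

    def test_matches_per_edge_regression_oracle(self, rng):
        nets = make_networks(rng, 25, 4)
        pheno = make_pheno(rng, 25)
        design = DesignSpec(contrast="score", covariates=("age",))
        out = cohens_f2(nets, pheno, design)
        X = np.column_stack([np.ones(25), pheno["score"], pheno["age"]])
        Z = X[:, [0, 2]]
        iu = np.triu_indices(4, 1)
        for i, j in zip(*iu):
            y = nets[:, i, j]
            rss_f = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
            rss_r = np.sum((y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]) ** 2)
            tss = np.sum((y - y.mean()) ** 2)
            r2f, r2r = 1 - rss_f / tss, 1 - rss_r / tss
            assert out["f2_matrix"][i, j] == pytest.approx(
                (r2f - r2r) / (1 - r2f), abs=1e-10
            )

    def test_subset_summary(self, rng):
        nets = make_networks(rng, 20, 5)
        pheno = make_pheno(rng, 20)
        out = cohens_f2(nets, pheno, DesignSpec(contrast="score"),
                        edge_subset=[("0", "1"), ("2", "3")])
        expected = np.mean([out["f2_matrix"][0, 1], out["f2_matrix"][2, 3]])
        assert out["subset_mean"] == pytest.approx(expected)


class TestSubnetworkReport:
    def _result(self, rng):
        nets = make_networks(rng, 15, 5)
        pheno = make_pheno(rng, 15)
        return (
            permutation_fwe(nets, pheno, DesignSpec(contrast="score"),
                            threshold=0.5, n_perm=100, seed=0),
            nets,
            pheno,
        )

    def _meta(self, n=5):
        return pd.DataFrame(
            {
                "node_id": [str(i) for i in range(n)],
                "x": np.arange(n), "y": np.arange(n), "z": np.arange(n),
                "system": ["visual"] * n,
            }
        )

    def test_degrees_satisfy_handshake_lemma(self, rng):
        res, nets, pheno = self._result(rng)
        node_df, comp_df = subnetwork_report(res, self._meta())
        for ci, comp in enumerate(res.components):
            degs = node_df.loc[node_df["component"] == ci, "degree"]
            assert degs.sum() == 2 * comp.extent

    def test_hub_degree(self):
        from dynfc.nbs import NbsComponent, NbsComponentResult

        res = NbsComponentResult(
            threshold=5.0,
            components=[NbsComponent(
                edges=[("0", "1"), ("0", "2"), ("0", "3")], extent=3,
                fwe_p=0.01)],
            n_permutations=100, stat_matrix=np.zeros((5, 5)),
            edge_t=np.zeros((5, 5)), node_ids=[str(i) for i in range(5)],
        )
        node_df, _ = subnetwork_report(res, self._meta())
        hub = node_df.set_index("node_id").loc["0", "degree"]
        assert hub == 3

    def test_empty_components_empty_tables(self):
        from dynfc.nbs import NbsComponentResult

        res = NbsComponentResult(
            threshold=5.0, components=[], n_permutations=100,
            stat_matrix=np.zeros((3, 3)), edge_t=np.zeros((3, 3)),
            node_ids=["0", "1", "2"],
        )
        node_df, comp_df = subnetwork_report(res, self._meta(3))
        assert node_df.empty and comp_df.empty

    def test_unknown_node_rejected(self, rng):
        from dynfc.nbs import NbsComponent, NbsComponentResult

        res = NbsComponentResult(
            threshold=5.0,
            components=[NbsComponent(edges=[("0", "99")], extent=1,
                                     fwe_p=0.5)],
            n_permutations=100, stat_matrix=np.zeros((3, 3)),
            edge_t=np.zeros((3, 3)), node_ids=["0", "1", "99"],
        )
        with pytest.raises(ValueError, match="unknown node"):
            subnetwork_report(res, self._meta(3))
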