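import numpy as np
import pandas as pd
import pytest

from limnoch4 import regression as reg
from limnoch4.community import rarefy
from limnoch4.config import SyntheticConfig
from limnoch4.synthetic import generate_core_chemistry, generate_otu_table


def random_xy(seed, n=30, p=6, active=(0,), noise=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
    )
    y = X.iloc[:, list(active)].sum(axis=1) + rng.normal(0, noise, n)
    return X, y.to_numpy()


class TestPlsr:
    def test_single_predictive_column_r2_one(self):
        """y exactly linear in one column (others orthogonal): 1 component
        suffices for a perfect fit and that variable has maximal VIP."""
        rng = np.random.default_rng(0)
        A = rng.normal(size=(20, 4))
        A -= A.mean(axis=0)
        # orthogonalise the distractor columns against the signal column
        b = A[:, 1]
        for j in (0, 2, 3):
            A[:, j] -= (A[:, j] @ b) / (b @ b) * b
        X = pd.DataFrame(A, columns=list("abcd"))
        y = 3.0 * b + 1.0
        m = reg.PLSRegressionVIP(n_components=1).fit(X, y)
        assert m.r2_ == pytest.approx(1.0, abs=1e-10)
        assert m.vip_.idxmax() == "b"

    def test_full_rank_equals_ols(self):
        """With as many components as the rank of X, PLSR reproduces OLS."""
        X, y = random_xy(1, n=25, p=5, active=(0, 2), noise=0.5)
        m = reg.PLSRegressionVIP(n_components=5).fit(X, y)
        ols = reg.fit_mlr(X, y)
        assert np.allclose(m.predict(X), ols.predict(X), rtol=1e-8, atol=1e-8)

    def test_vip_normalisation(self):
        X, y = random_xy(2, n=30, p=8, active=(0, 1), noise=0.3)
        m = reg.PLSRegressionVIP(n_components=3).fit(X, y)
        assert (m.vip_**2).sum() == pytest.approx(len(X.columns), rel=1e-9)

    def test_vip_closed_form_orthonormal_single_signal(self):
        """Orthonormal X, one predictive column, 1 component: VIP_j = sqrt(p)."""
        n, p = 16, 4
        A = np.random.default_rng(3).normal(size=(n, p))
        A -= A.mean(axis=0)  # centered columns stay centered through QR
        Q, _ = np.linalg.qr(A)
        X = pd.DataFrame(Q, columns=list("abcd"))
        y = Q[:, 2].copy()
        m = reg.PLSRegressionVIP(n_components=1, scale=False).fit(X, y)
        assert m.vip_["c"] == pytest.approx(2.0, abs=1e-8)
        others = m.vip_.drop("c")
        assert (others < 1e-6).all()

    def test_identical_copies_all_vip_one(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=20)
        X = pd.DataFrame({f"c{j}": col for j in range(5)})
        y = 2 * col + rng.normal(0, 0.01, 20)
        m = reg.PLSRegressionVIP(n_components=1).fit(X, y)
        assert np.allclose(m.vip_, 1.0, atol=1e-10)

    def test_column_scaling_invariance(self):
        X, y = random_xy(5, n=30, p=6, active=(1, 3), noise=0.4)
        m1 = reg.PLSRegressionVIP(n_components=3).fit(X, y)
        X2 = X.copy()
        X2["x1"] *= 1234.5
        m2 = reg.PLSRegressionVIP(n_components=3).fit(X2, y)
        assert m2.r2_ == pytest.approx(m1.r2_, rel=1e-9)
        assert np.allclose(m2.vip_, m1.vip_, rtol=1e-9)

    def test_matches_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_xy(6, n=40, p=10, active=(0, 4, 7), noise=0.5)
        for k in (1, 2, 4):
            ours = reg.PLSRegressionVIP(n_components=k).fit(X, y)
            sk = PLSRegression(n_components=k, scale=True).fit(X.to_numpy(), y)
            assert np.allclose(
                ours.predict(X), sk.predict(X.to_numpy()).ravel(), atol=1e-8
            )

    def test_zero_variance_column_dropped(self):
        X, y = random_xy(7)
        X["flat"] = 3.0
        with pytest.warns(UserWarning, match="flat"):
            m = reg.PLSRegressionVIP(n_components=2).fit(X, y)
        assert "flat" not in m.vip_.index

    def test_auto_components_avoid_overfitting_noise(self):
        """Adding pure-noise columns must not inflate r2 under LOO-PRESS."""
        gains = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = random_xy(seed, n=21, p=6, active=(0, 1), noise=0.5)
            base = reg.PLSRegressionVIP(n_components="auto").fit(X, y)
            Xn = X.copy()
            for j in range(30):
                Xn[f"noise{j}"] = rng.normal(size=21)
            full = reg.PLSRegressionVIP(n_components="auto").fit(Xn, y)
            gains.append(full.r2_ - base.r2_)
        assert np.median(gains) < 0.15

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        m = reg.PLSRegressionVIP(n_components=3, scale=False)
        c = clone(m)
        assert c.get_params() == m.get_params()


class TestMlr:
    def test_exact_line(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"x": x})
        m = reg.fit_mlr(X, 2 * x + 1)
        assert m.r2_ == pytest.approx(1.0)
        assert m.adj_r2_ == pytest.approx(1.0)
        assert m.coef_["x"] == pytest.approx(2.0)

    def test_adjusted_r2_formula(self):
        """adj r2 = 1 - (1-r2)(n-1)/(n-p-1); n=21, p=6, r2=0.672 -> 0.531."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(21, 6)), columns=list("abcdef"))
            y = X["a"].to_numpy() + rng.normal(0, 1.0, 21)
            m = reg.fit_mlr(X, y)
            expect = 1 - (1 - m.r2_) * 20 / 14
            assert m.adj_r2_ == pytest.approx(expect, rel=1e-9)
        assert 1 - (1 - 0.672) * 20 / 14 == pytest.approx(0.5314, abs=1e-3)

    def test_null_adjusted_r2_centered_on_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(500):
            X = pd.DataFrame(rng.normal(size=(21, 6)))
            y = rng.normal(size=21)
            vals.append(reg.fit_mlr(X, y).adj_r2_)
        assert abs(np.mean(vals)) < 0.05

    def test_rank_deficient_names_collinear_columns(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=12)})
        X["b"] = 2 * X["a"]
        X["c"] = rng.normal(size=12)
        with pytest.raises(reg.ModelError, match="b|a"):
            reg.fit_mlr(X, rng.normal(size=12))

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(5, 5)))
        with pytest.raises(reg.ModelError):
            reg.fit_mlr(X, rng.normal(size=5))


class TestAssembly:
    @pytest.fixture(scope="class")
    def assembled(self):
        cfg = SyntheticConfig(seed=5)
        chem = generate_core_chemistry(cfg)
        rare = rarefy(generate_otu_table(cfg), depth=cfg.rarefaction_depth, seed=5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vm = reg.assemble_variables(rare, chem)
        return rare, chem, vm

    def test_abiotic_block_present_and_ch4_excluded(self, assembled):
        _, _, vm = assembled
        abiotic = vm.provenance[vm.provenance == "abiotic"].index
        assert sorted(abiotic) == sorted(reg.ABIOTIC_VARS)
        assert "CH4_uM" not in vm.X.columns
        assert "d13C_CH4" not in vm.X.columns

    def test_strict_one_percent_threshold(self):
        counts = pd.DataFrame(
            {"at1pct": [10, 10], "above": [11, 10], "rest": [979, 980]},
            index=["s1", "s2"],
        )
        from limnoch4.community import OtuTable

        tax = pd.Series(
            {
                "at1pct": "Bacteria;P1;c",
                "above": "Bacteria;P2;c",
                "rest": "Bacteria;P3;c",
            }
        )
        meta = pd.DataFrame(
            {"core": "c", "lake": "MH", "zone": ["edge", "edge"],
             "depth_cm": [4.0, 8.0]},
            index=["s1", "s2"],
        )
        table = OtuTable(counts, tax, meta)
        chem = pd.DataFrame(
            {
                "core": "c", "depth_cm": [4.0, 8.0], "TOC_pct": [8.0, 7.5],
                "d13C_TOC": [-28.0, -27.8], "DIC_uM": [800.0, 900.0],
                "S_pct": [0.4, 0.5], "TOC_TS": [20.0, 15.0],
                "CH4_uM": [100.0, 150.0],
            },
            index=["s1", "s2"],
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vm = reg.assemble_variables(table, chem)
        otu_cols = vm.provenance[vm.provenance == "otu_gt1pct"].index
        assert "above" in otu_cols      # 1.1% in s1: strictly above threshold
        assert "at1pct" not in otu_cols  # exactly 1.0% everywhere: excluded

    def test_unmatched_samples_error_lists_keys(self, assembled):
        rare, chem, _ = assembled
        short = chem.drop(index=chem.index[:2])
        with pytest.raises(reg.ModelError, match=chem.index[0]):
            reg.assemble_variables(rare, short)

    def test_mag_proxy_by_otu_and_pattern(self, assembled):
        rare, chem, _ = assembled
        rel = rare.relative_abundance() * 100
        # pick a low-abundance OTU so the proxy is not a duplicate of an
        # existing >1% OTU column (duplicates are collapsed by design)
        low = next(o for o in rare.otus if rel[o].max() <= 1.0)
        mags = {
            "Bin1": {"otu": low},
            "Methanoregula": {"pattern": "Methanoregula"},
        }
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vm = reg.assemble_variables(rare, chem, mag_lineages=mags)
        assert np.allclose(vm.X["mag:Bin1"], rel[low])
        assert (vm.provenance == "mag_lineage_sum").sum() == 2

    def test_duplicate_columns_collapsed(self, assembled):
        _, _, vm = assembled
        assert not vm.X.T.duplicated().any()

    def test_missing_chemistry_interpolated(self, assembled):
        rare, chem, _ = assembled
        holed = chem.copy()
        holed.loc[holed.index[3], "TOC_pct"] = np.nan
        import warnings

        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            vm = reg.assemble_variables(rare, holed)
        assert not vm.X["TOC"].isna().any()


class TestCompareModels:
    def test_duplicate_suites_identical_metrics(self):
        cfg = SyntheticConfig(seed=9)
        chem = generate_core_chemistry(cfg)
        rare = rarefy(generate_otu_table(cfg), depth=cfg.rarefaction_depth, seed=9)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vm = reg.assemble_variables(rare, chem)
            out = reg.compare_models(
                vm, suites={"a": ("abiotic",), "b": ("abiotic",)}
            )
        assert out.loc["a", "plsr_r2"] == pytest.approx(out.loc["b", "plsr_r2"])
        assert out.loc["a", "mlr_adj_r2"] == pytest.approx(out.loc["b", "mlr_adj_r2"])

    def test_empty_suite_skipped_with_warning(self):
        cfg = SyntheticConfig(seed=9)
        chem = generate_core_chemistry(cfg)
        rare = rarefy(generate_otu_table(cfg), depth=cfg.rarefaction_depth, seed=9)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vm = reg.assemble_variables(rare, chem)
        with pytest.warns(UserWarning, match="nope"):
            out = reg.compare_models(
                vm, suites={"ok": ("abiotic",), "nope": ("no_such_tag",)}
            )
        assert list(out.index) == ["ok"]
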