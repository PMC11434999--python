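import numpy as np
import pandas as pd
import pytest

from faerspv.disproportionality import ContingencyTable2x2, haldane_correct, ror
from faerspv.errors import DegenerateDataError
from faerspv.faers_model import build_table_a
from faerspv.multivariate import (
    build_lnror_matrix,
    interpret_components,
    pca,
    regress_pc1_on_lnror,
    ward_cluster,
)

from _oracles import correlation_pca_oracle, ward_merge_oracle
from conftest import demo_frame, drug_frame, reac_frame


def frame(values, drugs=None, pts=None):
    values = np.asarray(values, dtype=float)
    drugs = drugs or [f"drug{i}" for i in range(values.shape[0])]
    pts = pts or [f"pt{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=drugs, columns=pts)


class TestLnRorMatrix:
    @pytest.fixture
    def tiny_table_a(self):
        """20 reports; dysgeusia and ageusia planted with identical
        per-drug co-occurrence so their lnROR cells must be equal."""
        n = 20
        demo = demo_frame([(str(i), str(i), 1, 60, "YR", "F") for i in range(n)])
        drug = drug_frame(
            [(str(i), "alphanib") for i in range(6)]
            + [(str(i), "othermed") for i in range(6, n)]
        )
        reac_rows = []
        for i in range(4):  # both PTs co-occur with alphanib in the same reports
            reac_rows += [(str(i), "dysgeusia"), (str(i), "ageusia")]
        for i in range(8, 14):
            reac_rows += [(str(i), "dysgeusia"), (str(i), "ageusia")]
        reac_rows += [(str(i), "nausea") for i in range(n)]
        return build_table_a(demo, drug, reac_frame(reac_rows))

    def test_identical_cooccurrence_gives_equal_cells(self, tiny_table_a):
        m = build_lnror_matrix(tiny_table_a, ["alphanib"], pt_min_reports=1)
        assert m.values.loc["alphanib", "dysgeusia"] == pytest.approx(
            m.values.loc["alphanib", "ageusia"]
        )

    def test_cells_are_corrected_lnror(self, tiny_table_a):
        m = build_lnror_matrix(tiny_table_a, ["alphanib"], pt_min_reports=1)
        # hand count: alphanib in 6 reports, dysgeusia in 10, overlap 4
        expected = ror(haldane_correct(ContingencyTable2x2(4, 2, 6, 8)))[1]
        assert m.values.loc["alphanib", "dysgeusia"] == pytest.approx(expected)

    def test_all_cells_finite_after_correction(self, tiny_table_a):
        m = build_lnror_matrix(
            tiny_table_a, ["alphanib", "othermed"], pt_min_reports=1
        )
        assert np.isfinite(m.values.to_numpy()).all()

    def test_report_count_floor_filters_columns(self, tiny_table_a):
        m = build_lnror_matrix(tiny_table_a, ["alphanib"], pt_min_reports=10)
        assert set(m.pts) == {"dysgeusia", "ageusia"}  # 10 reports each
        with pytest.raises(DegenerateDataError):
            build_lnror_matrix(tiny_table_a, ["alphanib"], pt_min_reports=11)

    def test_zero_cooccurrence_is_negative_cell(self):
        n = 30
        demo = demo_frame([(str(i), str(i), 1, 60, "YR", "F") for i in range(n)])
        drug = drug_frame(
            [(str(i), "alphanib") for i in range(5)]
            + [(str(i), "othermed") for i in range(5, n)]
        )
        reac = reac_frame(
            [(str(i), "dysgeusia") for i in range(5, 15)]
            + [(str(i), "nausea") for i in range(n)]
        )
        table_a = build_table_a(demo, drug, reac)
        m = build_lnror_matrix(table_a, ["alphanib"], pt_min_reports=1)
        cell = m.values.loc["alphanib", "dysgeusia"]
        assert np.isfinite(cell) and cell < 0


class TestWardCluster:
    def test_identical_profiles_merge_first_at_height_zero(self):
        df = frame([[1.0, 2.0], [5.0, 0.0], [1.0, 2.0], [9.0, 9.0]])
        result = ward_cluster(df, 2)
        first = result.merge_sets()[0]
        assert first == frozenset([frozenset([0]), frozenset([2])])
        assert result.heights()[0] == pytest.approx(0.0)

    def test_k_equal_one_and_k_too_large(self):
        df = frame(np.arange(12).reshape(4, 3))
        assert ward_cluster(df, 1).assignment.nunique() == 1
        with pytest.raises(ValueError):
            ward_cluster(df, 5)

    @pytest.mark.parametrize("n_rows", [2, 4, 5, 7])
    def test_merge_sequence_matches_exhaustive_oracle(self, n_rows):
        rng = np.random.default_rng(n_rows)
        for rep in range(20):
            X = rng.normal(size=(n_rows, 4))
            result = ward_cluster(frame(X), 1)
            assert result.merge_sets() == ward_merge_oracle(X)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        result = ward_cluster(frame(rng.normal(size=(12, 5))), 3)
        heights = result.heights()
        assert (np.diff(heights) >= -1e-12).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        df = frame(rng.normal(size=(10, 4)))
        perm = rng.permutation(10)
        shuffled = df.iloc[perm]
        a = ward_cluster(df, 3).assignment
        b = ward_cluster(shuffled, 3).assignment
        # same partition of drug names, up to cluster relabeling
        groups_a = {tuple(sorted(a.index[a == k])) for k in a.unique()}
        groups_b = {tuple(sorted(b.index[b == k])) for k in b.unique()}
        assert groups_a == groups_b

    def test_newick_export_contains_all_leaves(self):
        df = frame(np.arange(20).reshape(5, 4))
        text = ward_cluster(df, 2).to_newick()
        assert text.endswith(";")
        for name in df.index:
            assert name in text


class TestPca:
    def test_perfectly_correlated_columns_load_equally(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        df = frame(np.column_stack([x, 2 * x + 3, rng.normal(size=40)]))
        result = pca(df)
        loadings = result.loadings["PC1"]
        assert result.explained_fraction[0] >= 1 / 3
        assert abs(loadings.iloc[0]) == pytest.approx(abs(loadings.iloc[1]), abs=1e-9)

    def test_matches_correlation_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        for rep in range(5):
            X = rng.normal(size=(20, 7))
            result = pca(frame(X))
            w, V = correlation_pca_oracle(X)
            assert np.allclose(result.eigenvalues, w, atol=1e-8)
            for j in range(7):
                v = result.loadings.iloc[:, j].to_numpy()
                u = V[:, j]
                assert np.allclose(v, u, atol=1e-8) or np.allclose(v, -u, atol=1e-8)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        result = pca(frame(rng.normal(size=(15, 6))))
        assert result.explained_fraction.sum() == pytest.approx(1.0)

    def test_reconstruction_from_scores_and_loadings(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 5))
        result = pca(frame(X))
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        assert np.allclose(recon, Z, atol=1e-8)

    def test_constant_column_names_the_pt(self):
        df = frame(np.column_stack([np.ones(10), np.arange(10)]), pts=["flatpt", "varpt"])
        with pytest.raises(DegenerateDataError, match="flatpt"):
            pca(df)


class TestInterpretation:
    def test_score_identical_column_has_unit_correlation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        result = pca(frame(X))
        df = frame(X)
        df["echo"] = result.component(1).to_numpy()  # column equal to PC1 scores
        table = interpret_components(result, df, components=[1])
        echo_r = table.loc[table["pt"] == "echo", "r"].iloc[0]
        assert echo_r == pytest.approx(1.0)

    def test_correlations_match_textbook_formula(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        result = pca(frame(X))
        table = interpret_components(result, frame(X), components=[1, 2])
        for _, row in table.iterrows():
            s = result.component(int(row["component"])).to_numpy()
            y = X[:, int(row["pt"][2:])]
            sx, sy = s - s.mean(), y - y.mean()
            r_direct = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
            assert row["r"] == pytest.approx(r_direct, abs=1e-12)


class TestRegression:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 4))
        result = pca(frame(X))
        overall = (result.component(1) - 1.0) / 2.0  # PC1 = 2*overall + 1
        fit = regress_pc1_on_lnror(result, overall)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_r_squared_matches_direct_sums(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        result = pca(frame(X))
        overall = pd.Series(rng.normal(size=20), index=result.scores.index)
        fit = regress_pc1_on_lnror(result, overall)
        y = result.component(1).to_numpy()
        pred = fit.intercept + fit.slope * overall.to_numpy()
        ss_res = ((y - pred) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot)

    def test_too_few_drugs_rejected(self):
        df = frame(np.arange(12).reshape(4, 3).astype(float) + np.eye(4, 3))
        result = pca(df)
        with pytest.raises(DegenerateDataError):
            regress_pc1_on_lnror(result, pd.Series({"drug0": 1.0, "drug1": 2.0}))
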