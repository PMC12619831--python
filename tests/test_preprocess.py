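"""Preprocessing chain: each step against brute-force oracles, chain-order
enforcement, and the frozen-parameter (no-leakage) transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metabopanel.preprocess import (
    ChainOrderError,
    MetaboliteTable,
    PreprocessError,
    PreprocessPipeline,
    apply_frozen,
    creatinine_normalize,
    filter_missing,
    impute_lod,
    log_transform,
    pareto_scale,
)

from conftest import make_table


def random_censored_table(seed, n=20, p=8, missing_rate=0.15):
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.normal(0.5, 1.0, size=(n, p)))
    mask = rng.random((n, p)) < missing_rate
    mask[0] = False   # keep at least one positive observation per metabolite
    mask[:, 0] = False  # one fully observed metabolite survives any threshold
    vals[mask] = np.nan
    return make_table(vals, creatinine=np.exp(rng.normal(1.0, 0.3, n)))


class TestFilterMissing:
    def test_strict_greater_than_threshold(self):
        vals = np.ones((20, 3))
        vals[:5, 1] = np.nan   # 25% -> drop
        vals[:4, 2] = np.nan   # exactly 20% -> keep
        out, report = filter_missing(make_table(vals), 0.20)
        assert list(out.metabolite_ids) == ["M0", "M2"]
        assert report.removed == ["M1"]

    def test_no_missing_is_identity(self, toy_table):
        out, report = filter_missing(toy_table)
        pd.testing.assert_frame_equal(out.values, toy_table.values)
        assert report.removed == []

    @pytest.mark.parametrize("threshold", [0.0, 0.2, 0.5])
    def test_matches_bruteforce_recount(self, threshold):
        for seed in range(5):
            table = random_censored_table(seed)
            out, _ = filter_missing(table, threshold)
            expected = [
                m for m in table.metabolite_ids
                if np.mean(np.isnan(table.values[m].to_numpy())) <= threshold
            ]
            assert list(out.metabolite_ids) == expected

    def test_idempotent(self):
        table = random_censored_table(3, missing_rate=0.3)
        once, _ = filter_missing(table, 0.2)
        twice, _ = filter_missing(once, 0.2)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_removed_is_an_error(self):
        vals = np.full((4, 2), np.nan)
        vals[0] = 1.0  # 75% missing everywhere
        with pytest.raises(PreprocessError, match="threshold"):
            filter_missing(make_table(vals), 0.2)


class TestImputeLOD:
    def test_fifth_of_minimum_positive(self):
        vals = np.array([[np.nan, 2.0], [5.0, 4.0], [10.0, 8.0]])
        table, _ = filter_missing(make_table(vals), 0.5)
        out = impute_lod(table)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)  # 5/5
        assert out.values.iloc[1:, 0].tolist() == [5.0, 10.0]

    def test_no_missing_unchanged(self, toy_table):
        table, _ = filter_missing(toy_table)
        out = impute_lod(table)
        pd.testing.assert_frame_equal(out.values, toy_table.values)

    def test_matches_per_column_oracle(self):
        for seed in range(5):
            table, _ = filter_missing(random_censored_table(seed), 0.5)
            out = impute_lod(table)
            for m in table.metabolite_ids:
                col = table.values[m].to_numpy()
                fill = np.nanmin(np.where(col > 0, col, np.nan)) / 5.0
                expected = np.where(np.isnan(col), fill, col)
                np.testing.assert_allclose(out.values[m].to_numpy(), expected)

    def test_all_missing_column_is_an_error(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0], [np.nan, 2.0], [1.0, 3.0]])
        table = make_table(vals)
        table.steps_applied.append("filter_missing")  # bypass the filter
        with pytest.raises(PreprocessError, match="M0"):
            # M0 has one positive value; zero it out to break the precondition
            table.values.iloc[3, 0] = 0.0
            impute_lod(table)


class TestCreatinineNormalize:
    def test_unit_conversion(self):
        table = make_table([[10.0], [4.0]], creatinine=[2.0, 4.0])
        table.steps_applied += ["filter_missing", "impute_lod"]
        out = creatinine_normalize(table)
        assert out.values.iloc[:, 0].tolist() == [5.0, 1.0]

    def test_unit_creatinine_is_identity(self, toy_table):
        prepared = impute_lod(filter_missing(toy_table)[0])
        prepared.creatinine[:] = 1.0
        out = creatinine_normalize(prepared)
        pd.testing.assert_frame_equal(out.values, prepared.values)

    def test_matches_scalar_loop_oracle(self):
        table = impute_lod(filter_missing(random_censored_table(4))[0])
        out = creatinine_normalize(table)
        for i, s in enumerate(table.sample_ids):
            for j, m in enumerate(table.metabolite_ids):
                assert out.values.iloc[i, j] == pytest.approx(
                    table.values.iloc[i, j] / table.creatinine.loc[s])


class TestLogAndPareto:
    def _chain(self, table):
        return creatinine_normalize(impute_lod(filter_missing(table)[0]))

    def test_log_known_values(self):
        table = make_table([[np.e, 1.0], [1.0, np.e**2]])
        table.steps_applied += ["filter_missing", "impute_lod", "creatinine_normalize"]
        out = log_transform(table)
        np.testing.assert_allclose(out.values.to_numpy(), [[1, 0], [0, 2]], atol=1e-12)

    def test_log_error_reports_coordinates(self):
        table = make_table([[1.0, 1.0], [0.0, 1.0]])
        table.steps_applied += ["filter_missing", "impute_lod", "creatinine_normalize"]
        with pytest.raises(PreprocessError, match=r"S1.*M0"):
            log_transform(table)

    def test_pareto_hand_case(self):
        table = make_table([[1.0], [2.0], [3.0]])
        table.steps_applied += ["filter_missing", "impute_lod",
                                "creatinine_normalize", "log_transform"]
        out = pareto_scale(table)
        np.testing.assert_allclose(out.values.iloc[:, 0], [-1, 0, 1], atol=1e-12)
        assert out.scaling_params.loc["M0", "sd"] == pytest.approx(1.0)

    def test_pareto_constant_column_maps_to_zero(self):
        table = make_table([[4.0, 1.0], [4.0, 2.0], [4.0, 3.0]])
        table.steps_applied += ["filter_missing", "impute_lod",
                                "creatinine_normalize", "log_transform"]
        out = pareto_scale(table)
        assert (out.values["M0"] == 0).all()

    def test_pareto_single_sample_is_an_error(self):
        table = make_table([[1.0, 2.0]])
        table.steps_applied += ["filter_missing", "impute_lod",
                                "creatinine_normalize", "log_transform"]
        with pytest.raises(PreprocessError, match="2 samples"):
            pareto_scale(table)

    @given(st.integers(0, 10_000))
    def test_pareto_variance_identity(self, seed):
        """After Pareto scaling, each column's variance equals the original
        column's standard deviation (var(x/sqrt(s)) = s)."""
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(8, 4)))
        table = make_table(np.exp(x))
        scaled = pareto_scale(log_transform(creatinine_normalize(
            impute_lod(filter_missing(table)[0]))))
        np.testing.assert_allclose(
            scaled.values.var(ddof=1), x.std(ddof=1), atol=1e-9)


class TestChainOrder:
    def test_out_of_order_calls_error(self, toy_table):
        with pytest.raises(ChainOrderError):
            impute_lod(toy_table)  # before filter
        with pytest.raises(ChainOrderError):
            creatinine_normalize(filter_missing(toy_table)[0])  # before impute
        prepared = impute_lod(filter_missing(toy_table)[0])
        with pytest.raises(ChainOrderError):
            pareto_scale(creatinine_normalize(prepared))  # before log
        logged = log_transform(creatinine_normalize(prepared))
        with pytest.raises(ChainOrderError):
            log_transform(logged)  # twice

    def test_row_permutation_equivariance(self):
        table = random_censored_table(6)
        out = PreprocessPipeline().fit_transform(table)
        perm = np.random.default_rng(0).permutation(len(table.sample_ids))
        shuffled = MetaboliteTable(table.values.iloc[perm], table.lod,
                                   table.creatinine.iloc[perm])
        out_shuffled = PreprocessPipeline().fit_transform(shuffled)
        pd.testing.assert_frame_equal(out.values.iloc[perm], out_shuffled.values)


class TestApplyFrozen:
    def test_train_table_reproduces_fit_transform(self, toy_table):
        pipe = PreprocessPipeline()
        fitted = pipe.fit_transform(toy_table)
        again = pipe.transform(toy_table)
        pd.testing.assert_frame_equal(fitted.values, again.values)

    def test_duplicate_sample_gets_identical_row(self, toy_table):
        pipe = PreprocessPipeline()
        pipe.fit_transform(toy_table)
        clone = MetaboliteTable(
            toy_table.values.iloc[[0]].set_axis(["NEW"], axis=0),
            toy_table.lod,
            toy_table.creatinine.iloc[[0]].set_axis(["NEW"]),
        )
        row = pipe.transform(clone)
        np.testing.assert_allclose(
            row.values.iloc[0], pipe.fit_transform(toy_table).values.iloc[0],
            atol=1e-12)

    def test_frozen_differs_from_refit_on_shifted_split(self):
        rng = np.random.default_rng(12)
        a = make_table(np.exp(rng.normal(0.0, 1.0, (10, 4))))
        b = make_table(np.exp(rng.normal(2.0, 1.0, (10, 4))))
        pipe = PreprocessPipeline()
        pipe.fit_transform(a)
        frozen_b = pipe.transform(b)
        refit_b = PreprocessPipeline().fit_transform(b)
        assert not np.allclose(frozen_b.values, refit_b.values)

    def test_metabolite_mismatch_is_an_error(self, toy_table):
        pipe = PreprocessPipeline()
        pipe.fit_transform(toy_table)
        stripped = MetaboliteTable(
            toy_table.values.iloc[:, :3], toy_table.lod.iloc[:3],
            toy_table.creatinine)
        with pytest.raises(PreprocessError, match="lacks"):
            pipe.transform(stripped)
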