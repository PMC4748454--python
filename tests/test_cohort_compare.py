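import numpy as np
import pandas as pd
import pytest

from mirnaome.cohort_compare import (
    bh_adjust,
    bmi_correlation,
    compare_factor,
    encode_factor,
    heatmap_matrix,
    residualize,
    t_test_de,
)
from mirnaome.quantify import ExpressionMatrix


def make_meta(n=12, rng=None):
    rng = rng or np.random.default_rng(0)
    half = n // 2
    rows = []
    for i in range(n):
        sex = "F" if i < half else "M"
        rows.append({
            "subject_id": f"{'FA' if sex == 'F' else 'MA'}{i % half + 1:02d}",
            "sex": sex,
            "age": int(rng.integers(20, 65)),
            "smoking": "yes" if i % 3 == 0 else "no",
            "bmi": float(rng.uniform(19, 40)),
        })
    meta = pd.DataFrame(rows).set_index("subject_id")
    meta["obese"] = meta["bmi"] >= 30
    return meta


def make_expr(values, meta):
    df = pd.DataFrame(values, columns=meta.index)
    df.index = [f"m{i}" for i in range(df.shape[0])]
    return ExpressionMatrix(df)


class TestResidualize:
    def test_no_nuisance_factors_is_identity(self, rng):
        meta = make_meta()
        expr = make_expr(rng.random((5, 12)), meta)
        out = residualize(expr, meta, "sex", nuisance_factors=[])
        pd.testing.assert_frame_equal(out.expression, expr.expression)

    def test_pure_smoking_effect_removed_before_sex_test(self, rng):
        meta = make_meta()
        smoke = encode_factor(meta, "smoking").values
        expr = make_expr(np.tile(10 + 5 * smoke, (4, 1)), meta)
        adjusted = residualize(expr, meta, "sex", nuisance_factors=["smoking"])
        sex = encode_factor(meta, "sex").values
        for i in range(4):
            row = adjusted.expression.iloc[i].values
            assert abs(row[sex == 1].mean() - row[sex == 0].mean()) < 1e-10

    def test_residuals_orthogonal_to_eliminated_covariates(self, rng):
        meta = make_meta()
        expr = make_expr(rng.random((6, 12)) * 20, meta)
        adjusted = residualize(expr, meta, "sex")
        for factor in ("smoking", "obese"):
            x = encode_factor(meta, factor).values
            x = x - x.mean()
            for i in range(6):
                resid = adjusted.expression.iloc[i].values \
                    - adjusted.expression.iloc[i].mean()
                assert abs(np.dot(resid, x)) < 1e-8

    def test_confounded_design_rejected(self, rng):
        meta = make_meta()
        meta["smoking"] = np.where(meta["sex"] == "F", "yes", "no")
        meta["obese"] = meta["sex"] == "F"  # smoking == obese -> collinear
        expr = make_expr(rng.random((3, 12)), meta)
        with pytest.raises(ValueError, match="collinear|confounded"):
            residualize(expr, meta, "sex")


class TestTTestDE:
    def test_identical_groups_produce_no_calls(self):
        values = np.column_stack([[5.0, 1.0, 3.0]] * 8)
        meta = make_meta(8)
        expr = make_expr(values, meta)
        result = t_test_de(expr, [1, 1, 1, 1, 0, 0, 0, 0])
        assert not result.table["significant"].any()
        assert result.table["flagged"].all()  # zero variance in both groups

    def test_planted_difference_detected_with_correct_direction(self, rng):
        labels = np.array([1] * 6 + [0] * 6)
        base = rng.lognormal(0, 0.25, size=(5, 12))
        base[0, labels == 1] *= 4.0
        meta = make_meta(12)
        expr = make_expr(base, meta)
        result = t_test_de(expr, labels, group_names=("g1", "g0"))
        assert bool(result.table.loc["m0", "significant"])
        assert result.table.loc["m0", "direction"] == "up_in_g1"
        assert result.table.loc["m0", "fold_change"] > 1

    def test_significant_table_sorted_by_descending_fold_change(self, rng):
        labels = np.array([1] * 6 + [0] * 6)
        base = rng.lognormal(0, 0.1, size=(6, 12))
        base[0, labels == 1] *= 3.0
        base[1, labels == 1] *= 8.0
        expr = make_expr(base, make_meta(12))
        sig = t_test_de(expr, labels).significant
        folds = sig["fold_change"].values
        assert (np.diff(folds) <= 0).all()

    def test_groups_smaller_than_two_rejected(self, rng):
        expr = make_expr(rng.random((2, 4)), make_meta(4))
        with pytest.raises(ValueError, match="2 subjects"):
            t_test_de(expr, [1, 0, 0, 0])

    def test_bh_adjustment_is_monotone_and_bounded(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def test_permuted_labels_hold_type_i_error(rng):
    """Label permutations on null data call ~alpha of miRNAs significant."""
    meta = make_meta(12)
    expr = make_expr(rng.lognormal(0, 0.3, size=(400, 12)), meta)
    rates = []
    for seed in range(5):
        perm_rng = np.random.default_rng(seed)
        labels = perm_rng.permutation([1] * 6 + [0] * 6)
        result = t_test_de(expr, labels)
        rates.append(result.table["significant"].mean())
    rate = np.mean(rates)
    sd = np.sqrt(0.05 * 0.95 / (400 * 5))
    assert abs(rate - 0.05) < 4 * sd


class TestBMICorrelation:
    def test_perfect_linear_relation_gives_r_one(self):
        meta = make_meta(10)
        values = np.tile(2 * meta["bmi"].values + 3, (2, 1))
        expr = make_expr(values, meta)
        table = bmi_correlation(expr, meta)
        assert table.loc[("m0", "all"), "r"] == pytest.approx(1.0)

    def test_independent_expression_r_near_zero(self, rng):
        n = 200
        meta = make_meta(12)
        meta = pd.concat([meta] * 17)[:n]
        meta.index = [f"s{i}" for i in range(n)]
        meta["bmi"] = rng.uniform(19, 40, size=n)
        expr = make_expr(rng.random((3, n)), meta)
        table = bmi_correlation(expr, meta)
        assert abs(table.loc[("m0", "all"), "r"]) < 3 / np.sqrt(n)

    def test_planted_slope_recovered_over_seed_ensemble(self):
        """Noise calibrated for r ~ 0.65 at n=18: recovered within +-0.15
        averaged over seeds."""
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bmi = rng.uniform(19, 42, size=18)
            slope = 1.0
            sigma = slope * bmi.std() * np.sqrt(1 / 0.65**2 - 1)
            y = slope * bmi + rng.normal(0, sigma, size=18)
            meta = pd.DataFrame({
                "sex": ["F"] * 9 + ["M"] * 9, "age": 40,
                "smoking": "no", "bmi": bmi, "obese": bmi >= 30,
            }, index=[f"s{i}" for i in range(18)])
            meta.index.name = "subject_id"
            expr = make_expr(y[None, :] - y.min() + 1, meta)
            rs.append(bmi_correlation(expr, meta).loc[("m0", "all"), "r"])
        assert abs(np.mean(rs) - 0.65) < 0.15

    def test_zero_variance_flagged_nan(self):
        meta = make_meta(6)
        expr = make_expr(np.ones((1, 6)), meta)
        assert np.isnan(bmi_correlation(expr, meta).loc[("m0", "all"), "r"])

    def test_sex_stratification_reports_three_strata(self, rng):
        meta = make_meta(10)
        expr = make_expr(rng.random((2, 10)), meta)
        table = bmi_correlation(expr, meta, stratify_sex=True)
        assert set(table.loc["m0"].index) == {"all", "F", "M"}


def test_compare_factor_detects_planted_sex_effect(rng):
    meta = make_meta(12)
    sex = encode_factor(meta, "sex").values
    base = rng.lognormal(0, 0.2, size=(8, 12))
    base[2, sex == 1] *= 5.0
    expr = make_expr(base, meta)
    result = compare_factor(expr, meta, "sex")
    assert bool(result.table.loc["m2", "significant"])
    assert result.table.loc["m2", "direction"] == "up_in_F"


def test_heatmap_rows_standardized_and_clipped(rng):
    meta = make_meta(8)
    expr = make_expr(rng.random((4, 8)) * 30, meta)
    hm = heatmap_matrix(expr, ["m0", "m1"])
    assert hm.values.min() >= -2 and hm.values.max() <= 2
    raw = expr.expression.loc[["m0", "m1"]]
    z = raw.sub(raw.mean(axis=1), axis=0).div(raw.std(axis=1, ddof=1), axis=0)
    assert np.allclose(hm.values, z.clip(-2, 2).values)
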