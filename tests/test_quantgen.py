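"""ANOVA decomposition, heritability quotients, mass adjustment, post hoc
contrasts and glycemia classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteophen import quantgen as qg
from osteophen.errors import DesignError, MappingError, ValidationError

from conftest import brute_force_anova_ss


def _toy(strains, sexes, values):
    return pd.DataFrame({"strain": strains, "sex": sexes, "y": values})


def _balanced_toy():
    # 2 strains x 2 sexes x 2 reps, trait = 10 * [strain == A], no noise
    rows = []
    for strain in "AB":
        for sex in "FM":
            for _ in range(2):
                rows.append((strain, sex, 10.0 if strain == "A" else 0.0))
    return _toy(*zip(*rows))


class TestAnovaSS:
    def test_constant_trait_is_degenerate_with_zero_ss(self):
        df = _toy(list("AABB") * 2, list("FFMM") * 2, [5.0] * 8)
        d = qg.anova_ss(df, "y")
        assert d.degenerate
        assert d.ss_strain == d.ss_sex == d.ss_res == 0.0

    def test_constructed_effects_partition(self):
        d = qg.anova_ss(_balanced_toy(), "y")
        assert d.ss_strain == pytest.approx(200.0, abs=1e-9)
        assert d.ss_sex == pytest.approx(0.0, abs=1e-9)
        assert d.ss_res == pytest.approx(0.0, abs=1e-9)
        assert d.n_avg == 4.0

    def test_single_strain_raises_design_error(self):
        df = _toy(["A"] * 6, list("FFFMMM"), np.arange(6.0))
        with pytest.raises(DesignError):
            qg.anova_ss(df, "y")

    def test_single_sex_raises_design_error(self):
        df = _toy(list("AAABBB"), ["F"] * 6, np.arange(6.0))
        with pytest.raises(DesignError):
            qg.anova_ss(df, "y")

    @pytest.mark.parametrize("model", ["additive", "interaction"])
    @pytest.mark.parametrize("seed", range(8))
    def test_random_unbalanced_toys_match_projection_oracle(self, model, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 21)
        strains = rng.choice(list("ABC"), n)
        sexes = rng.choice(list("FM"), n)
        # guarantee an estimable design with filled cells
        strains[:6] = list("AABBCC")
        sexes[:6] = list("FMFMFM")
        y = rng.normal(size=n) + (strains == "A") * 2.0
        df = _toy(strains, sexes, y)
        d = qg.anova_ss(df, "y", model=model)
        oracle = brute_force_anova_ss(strains, sexes, y, model=model)
        scale = max(oracle["ss_res"], 1.0)
        assert d.ss_strain == pytest.approx(oracle["ss_strain"], abs=1e-8 * scale)
        assert d.ss_sex == pytest.approx(oracle["ss_sex"], abs=1e-8 * scale)
        assert d.ss_res == pytest.approx(oracle["ss_res"], abs=1e-8 * scale)
        if model == "interaction":
            assert d.ss_interaction == pytest.approx(
                oracle["ss_interaction"], abs=1e-8 * scale
            )

    def test_additive_balanced_partition_sums_to_total(self):
        rng = np.random.default_rng(0)
        df = _toy(list("AABB") * 4, list("FM") * 8, rng.normal(size=16))
        d = qg.anova_ss(df, "y")
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert d.ss_strain + d.ss_sex + d.ss_res == pytest.approx(total, rel=1e-9)

    def test_missing_values_dropped(self):
        df = _balanced_toy()
        df.loc[0, "y"] = np.nan
        d = qg.anova_ss(df, "y")
        assert d.n_obs == 7


class TestBroadSenseH2:
    def test_pure_strain_variance_gives_one(self):
        d = qg.AnovaDecomposition("t", 50.0, 0.0, 0.0, 7, 1, 10, 4.0, 32, "additive", "III")
        assert qg.broad_sense_h2(d).H2 == 1.0

    def test_zero_strain_variance_gives_zero(self):
        d = qg.AnovaDecomposition("t", 0.0, 5.0, 30.0, 7, 1, 10, 4.0, 32, "additive", "III")
        assert qg.broad_sense_h2(d).H2 == 0.0

    def test_quotient_formula_worked_example(self):
        # SS_strain=80 with n_avg=4 -> 20; SS_sex=5/df 1 -> 5; SS_res=30/df 10 -> 3
        d = qg.AnovaDecomposition("t", 80.0, 5.0, 30.0, 7, 1, 10, 4.0, 32, "additive", "III")
        r = qg.broad_sense_h2(d)
        assert (r.sigma2_strain, r.sigma2_sex, r.sigma2_res) == (20.0, 5.0, 3.0)
        assert r.H2 == pytest.approx(20.0 / 28.0)

    @given(
        ss=st.tuples(*[st.floats(0, 1e6) for _ in range(3)]),
        n_avg=st.floats(1.0, 100.0),
    )
    def test_h2_always_in_unit_interval(self, ss, n_avg):
        d = qg.AnovaDecomposition("t", *ss, 7, 1, 10, n_avg, 32, "additive", "III")
        assert 0.0 <= qg.broad_sense_h2(d).H2 <= 1.0

    def test_h2_table_sorted_descending(self, small_cohort):
        table, _ = small_cohort
        h2 = qg.h2_table(table, ["BMC", "PYD", "TMD"])
        assert (h2["H2"].diff().dropna() <= 0).all()


def _mass_table():
    rng = np.random.default_rng(2)
    rows = []
    for i, strain in enumerate("ABCDEFGH"):
        masses = 20.0 + 2.0 * i + rng.uniform(-3, 3, 12)
        for sex, mass in zip("FM" * 6, masses):
            rows.append((f"{strain}{sex}{mass:.3f}", "founder", strain, sex, mass, 2.0 * mass))
    return pd.DataFrame(
        rows, columns=["animal_id", "population", "strain", "sex", "body_mass", "y"]
    )


class TestMassAdjustment:
    def test_exact_allometry_recovers_slope_two_everywhere(self):
        df = _mass_table()
        model = qg.fit_mass_slopes(df, "y")
        for sl in model.slopes.values():
            assert not sl.zeroed
            assert sl.slope == pytest.approx(2.0, rel=1e-9)
        adj = qg.apply_mass_adjustment(df, "y", model)
        df = df.assign(adj=adj)
        for _, grp in df.groupby("strain"):
            assert grp["adj"].std() == pytest.approx(0.0, abs=1e-9)

    def test_grand_mean_mass_is_mean_of_strain_means(self):
        df = pd.DataFrame({
            "animal_id": list("abcdef"),
            "population": ["founder"] * 6,
            "strain": ["A"] * 3 + ["B"] * 3,
            "sex": list("FMF") * 2,
            "body_mass": [20.0, 25.0, 30.0, 30.0, 35.0, 40.0],
            "y": [1.0, 2.0, 1.5, 2.5, 2.0, 3.0],
        })
        model = qg.fit_mass_slopes(df, "y")
        assert model.grand_mean_mass == pytest.approx((25.0 + 35.0) / 2.0)

    def test_small_strain_zeroed_with_distinct_flag(self):
        df = _mass_table().iloc[:-11]  # leaves strain H with 1 animal
        model = qg.fit_mass_slopes(df, "y")
        assert model.slopes["H"].zeroed
        assert model.slopes["H"].reason == "insufficient_n"

    def test_adjustment_formula_worked_example(self):
        model = qg.AdjustmentModel(
            "y", {"A": qg.StrainSlope(2.0, 0.01, False, "", 9)}, grand_mean_mass=30.0
        )
        df = pd.DataFrame({"strain": ["A"], "body_mass": [35.0], "y": [100.0]})
        assert qg.apply_mass_adjustment(df, "y", model).iloc[0] == pytest.approx(90.0)

    def test_zeroed_strain_passes_through_unchanged(self):
        model = qg.AdjustmentModel(
            "y", {"A": qg.StrainSlope(0.0, 0.5, True, "p>0.20", 9)}, grand_mean_mass=30.0
        )
        df = pd.DataFrame({"strain": ["A"] * 3, "body_mass": [20.0, 30.0, 40.0],
                           "y": [1.0, 2.0, 3.0]})
        assert (qg.apply_mass_adjustment(df, "y", model) == df["y"]).all()

    def test_unknown_strain_raises_mapping_error(self):
        model = qg.AdjustmentModel(
            "y", {"A": qg.StrainSlope(1.0, 0.01, False, "", 9)}, grand_mean_mass=30.0
        )
        df = pd.DataFrame({"strain": ["Z"], "body_mass": [30.0], "y": [1.0]})
        with pytest.raises(MappingError):
            qg.apply_mass_adjustment(df, "y", model)

    def test_boundary_p_keeps_slope(self):
        # zeroing uses strict inequality: p == threshold retains the slope
        df = _mass_table()
        model = qg.fit_mass_slopes(df, "y", p_threshold=1.0)
        assert not any(sl.zeroed for sl in model.slopes.values())

    def test_adjustment_idempotent_on_noiseless_data(self):
        df = _mass_table()
        model = qg.fit_mass_slopes(df, "y")
        df = df.assign(y=qg.apply_mass_adjustment(df, "y", model))
        refit = qg.fit_mass_slopes(df, "y")
        for sl in refit.slopes.values():
            assert sl.zeroed or abs(sl.slope) < 1e-8


class TestCovariateSignificance:
    def test_trait_equal_to_mass_is_overwhelming(self):
        df = _mass_table()
        p, sig, flag = qg.covariate_significance(df, "y")
        assert p < 1e-10 and sig and flag == ""

    def test_constant_mass_flagged_degenerate(self):
        df = _mass_table().assign(body_mass=25.0)
        p, sig, flag = qg.covariate_significance(df, "y")
        assert flag == "degenerate" and np.isnan(p)


class TestPosthoc:
    def test_sidak_identity_for_single_contrast(self):
        assert qg.sidak_adjust(0.04, 1) == pytest.approx(0.04)

    @given(p=st.floats(0.0, 1.0), m1=st.integers(1, 50), m2=st.integers(1, 50))
    def test_sidak_monotone_in_family_size(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert qg.sidak_adjust(p, lo) <= qg.sidak_adjust(p, hi) + 1e-15

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=9)
        rows = []
        for strain in ("B6", "CAST"):
            for sex in "FM":
                for i, v in enumerate(base):
                    rows.append((f"{strain}{sex}{i}", "founder", strain, sex, 25.0, v))
        df = pd.DataFrame(rows, columns=["animal_id", "population", "strain", "sex",
                                         "body_mass", "y"])
        out = qg.strain_sex_posthoc(df, "y")
        assert (out["p_adj"] > 0.9).all()
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_large_shift_detected(self, small_cohort):
        table, _ = small_cohort
        shifted = table.copy()
        shifted.loc[shifted["strain"] == "NZO", "BMC"] += 10 * shifted["BMC"].std()
        out = qg.strain_sex_posthoc(shifted, "BMC")
        nzo = out[out["contrast"].str.startswith("NZO")]
        assert (nzo["p_adj"] < 0.05).all()

    def test_missing_reference_raises(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(Exception, match="absent"):
            qg.strain_sex_posthoc(table, "BMC", reference="C3H")


class TestGlycemia:
    @pytest.mark.parametrize(
        "fbg, expected",
        [(251.0, "hyperglycemic"), (250.0, "normal"), (100.0, "normal")],
    )
    def test_threshold_is_strict(self, fbg, expected):
        assert qg.classify_glycemia(fbg) == expected

    def test_array_input(self):
        out = qg.classify_glycemia(np.array([100.0, 300.0]))
        assert list(out) == ["normal", "hyperglycemic"]

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            qg.classify_glycemia(-1.0)
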