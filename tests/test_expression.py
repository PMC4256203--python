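import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sialoseq import expression
from sialoseq.expression import (
    build_contrasts,
    chi2_test,
    de_table,
    normalized_ratio,
    row_average_normalize,
    rpkm,
)
from sialoseq.read_processing import LibraryCounts


def chi2_closed_form(r1, R1, r2, R2):
    """Independent textbook 2x2 oracle: chi2 = N(ad-bc)^2/[(a+b)(c+d)(a+c)(b+d)]."""
    a, b, c, d = r1, R1 - r1, r2, R2 - r2
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return N * (a * d - b * c) ** 2 / denom


class TestRpkm:
    def test_zero_count_gives_zero(self):
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_round_numbers(self):
        assert rpkm(100, 1000, 10**6) == pytest.approx(100.0)

    def test_inverse_proportionality_to_total(self):
        assert rpkm(100, 1000, 2 * 10**6) == pytest.approx(rpkm(100, 1000, 10**6) / 2)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            rpkm(5, 300, 0)


class TestNormalizedRatio:
    def test_formula_with_zero_opposite_reads(self):
        r12, r21 = normalized_ratio(10, 1000, 0, 1000)
        assert r12 == pytest.approx(10.0)
        assert r21 == 0.0

    def test_both_zero(self):
        assert normalized_ratio(0, 1000, 0, 1000) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        r12, _ = normalized_ratio(50, 2000, 5, 1000)
        assert r12 == pytest.approx(50 * 1000 / (2000 * 6))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalized_ratio(5, 0, 1, 10)
        with pytest.raises(ValueError):
            normalized_ratio(11, 10, 1, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        r1=st.integers(0, 500), r2=st.integers(0, 500),
        extra1=st.integers(1, 10_000), extra2=st.integers(1, 10_000),
    )
    def test_antisymmetry_under_group_swap(self, r1, r2, extra1, extra2):
        R1, R2 = r1 + extra1, r2 + extra2
        fwd = normalized_ratio(r1, R1, r2, R2)
        rev = normalized_ratio(r2, R2, r1, R1)
        assert fwd == (rev[1], rev[0])


class TestChi2:
    def test_symmetric_table_is_null(self):
        chi2, p = chi2_test(25, 1000, 25, 1000)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        chi2, _ = chi2_test(30, 1000, 10, 1000)
        assert chi2 == pytest.approx(chi2_closed_form(30, 1000, 10, 1000), abs=1e-9)

    def test_thousand_random_tables_match_oracle(self, rng):
        for _ in range(1000):
            R1, R2 = int(rng.integers(1, 5000)), int(rng.integers(1, 5000))
            r1, r2 = int(rng.integers(0, R1 + 1)), int(rng.integers(0, R2 + 1))
            chi2, _ = chi2_test(r1, R1, r2, R2)
            assert chi2 == pytest.approx(chi2_closed_form(r1, R1, r2, R2), abs=1e-9)

    def test_degenerate_table(self):
        assert chi2_test(0, 10, 0, 10) == (0.0, 1.0)

    def test_chi2_grows_with_imbalance(self):
        values = [chi2_test(r, 1000, 10, 1000)[0] for r in (10, 20, 40, 80)]
        assert values == sorted(values)
        ps = [chi2_test(r, 1000, 10, 1000)[1] for r in (10, 20, 40, 80)]
        assert ps == sorted(ps, reverse=True)


def _lc(lib, counts):
    lc = LibraryCounts(library_id=lib, counts=dict(counts))
    lc.distinct_mapped = sum(counts.values())
    lc.reads_in = lc.distinct_mapped
    return lc


@pytest.fixture
def ten_library_design():
    rows = []
    for region in ("Arg", "BolCol", "BolNat", "Chile", "Peru"):
        for stage, suffix in (("nymph", "N"), ("adult", "A")):
            rows.append({"library_id": f"{region}-{suffix}", "stage": stage, "region": region})
    return pd.DataFrame(rows)


class TestContrasts:
    def test_study_design_yields_six_contrasts(self, ten_library_design, rng):
        counts = {
            row.library_id: _lc(row.library_id, {"c1": int(rng.integers(1, 50)), "c2": 7})
            for row in ten_library_design.itertuples()
        }
        contrasts = build_contrasts(counts, ten_library_design)
        names = [c.name for c in contrasts]
        assert names[0] == "nymph_vs_adult"
        assert len(contrasts) == 6
        assert sum(n.endswith("_vs_rest") for n in names) == 5

    def test_single_library_groups_reduce_to_raw_comparison(self):
        design = pd.DataFrame(
            [
                {"library_id": "L1", "stage": "nymph", "region": "A"},
                {"library_id": "L2", "stage": "adult", "region": "B"},
            ]
        )
        counts = {"L1": _lc("L1", {"c1": 9}), "L2": _lc("L2", {"c1": 4})}
        stage = build_contrasts(counts, design)[0]
        assert stage.r1["c1"] == 9 and stage.r2["c1"] == 4
        assert stage.R1 == 9 and stage.R2 == 4

    def test_group_totals_partition_grand_total(self, ten_library_design, rng):
        counts = {
            row.library_id: _lc(
                row.library_id, {f"c{j}": int(rng.integers(0, 40)) for j in range(8)}
            )
            for row in ten_library_design.itertuples()
        }
        grand = sum(lc.total_mapped for lc in counts.values())
        for contrast in build_contrasts(counts, ten_library_design):
            assert contrast.R1 + contrast.R2 == grand
            assert contrast.r1.sum() + contrast.r2.sum() == grand

    def test_region_without_libraries_is_an_error(self):
        design = pd.DataFrame(
            [
                {"library_id": "L1", "stage": "nymph", "region": "A"},
                {"library_id": "L2", "stage": "adult", "region": "B"},
            ]
        )
        counts = {"L1": _lc("L1", {"c1": 3}), "L2": _lc("L2", {"c1": 5})}
        with pytest.raises(ValueError, match="no libraries"):
            build_contrasts(counts, design, regions=["A", "B", "C"])

    def test_region_covering_all_libraries_yields_no_contrast(self):
        design = pd.DataFrame(
            [
                {"library_id": "L1", "stage": "nymph", "region": "A"},
                {"library_id": "L2", "stage": "adult", "region": "A"},
            ]
        )
        counts = {"L1": _lc("L1", {"c1": 3}), "L2": _lc("L2", {"c1": 5})}
        names = [c.name for c in build_contrasts(counts, design)]
        assert names == ["nymph_vs_adult"]


class TestCalls:
    def _contrast(self, r1, r2, R1=100_000, R2=100_000):
        idx = pd.Index([f"c{i}" for i in range(len(r1))], name="cds_id")
        return expression.Contrast(
            "test", ["g1"], ["g2"],
            pd.Series(r1, index=idx), pd.Series(r2, index=idx), R1, R2,
        )

    def test_fold_and_significance_both_required(self):
        # high ratio but weak evidence -> ns; strong evidence but low ratio -> ns
        c = self._contrast([3, 900], [0, 200])
        df = de_table(c, fold=10, alpha=0.05, mtc=None)
        assert df.loc["c0", "ratio_1over2"] >= 3  # tiny counts, ratio 3
        assert df.loc["c0", "call"] == "ns"
        assert df.loc["c1", "p"] < 1e-10 and df.loc["c1", "ratio_1over2"] < 10
        assert df.loc["c1", "call"] == "ns"

    def test_clear_overexpression_is_called_both_directions(self):
        c = self._contrast([500, 0], [0, 500])
        df = de_table(c, fold=10, alpha=0.05)
        assert df.loc["c0", "call"] == "over_in_1"
        assert df.loc["c1", "call"] == "over_in_2"

    def test_permissive_thresholds_call_everything_reaching_fold(self):
        c = self._contrast([40, 0, 3], [0, 25, 3])
        df = de_table(c, fold=1, alpha=1, mtc=None)
        for cds_id in df.index:
            row = df.loc[cds_id]
            if max(row["ratio_1over2"], row["ratio_2over1"]) >= 1 and row["p"] < 1:
                assert row["call"] != "ns"

    def test_bonferroni_reduces_calls(self):
        r1 = [12] + [1] * 400
        r2 = [0] + [1] * 400
        c = self._contrast(r1, r2, R1=10_000, R2=10_000)
        raw = de_table(c, fold=10, alpha=0.05, mtc=None)
        adj = de_table(c, fold=10, alpha=0.05, mtc="bonferroni")
        assert raw.loc["c0", "call"] == "over_in_1"
        assert adj.loc["c0", "call"] == "ns"  # p*m crosses alpha

    def test_consistent_with_scalar_chi2(self):
        c = self._contrast([30, 11], [10, 3], R1=1000, R2=900)
        df = de_table(c)
        for cds_id, row in df.iterrows():
            chi2, p = chi2_test(int(row.r1), 1000, int(row.r2), 900)
            assert row["chi2"] == pytest.approx(chi2, abs=1e-9)
            assert row["p"] == pytest.approx(p, abs=1e-12)


class TestClassSummary:
    def test_hand_computed_mean_and_se(self):
        df = expression.class_summary(
            ["a", "b", "c"],
            {"a": 10.0, "b": 20.0, "c": 5.0},
            {"a": 1.0, "b": 2.0, "c": 3.0},
            {"a": "Secreted", "b": "Secreted", "c": "Viral"},
        )
        secreted = df[df.class_label == "Secreted"].iloc[0]
        assert secreted.mean_rpkm_group1 == pytest.approx(15.0)
        assert secreted.se_rpkm_group1 == pytest.approx(np.std([10, 20], ddof=1) / np.sqrt(2))
        viral = df[df.class_label == "Viral"].iloc[0]
        assert np.isnan(viral.se_rpkm_group1)  # single CDS -> SE blank

    def test_identical_members_have_zero_se(self):
        df = expression.class_summary(
            ["a", "b"], {"a": 7.0, "b": 7.0}, {"a": 2.0, "b": 2.0}, {"a": "S", "b": "S"}
        )
        assert df.iloc[0].se_rpkm_group1 == 0.0


class TestRowNormalize:
    def test_constant_row(self):
        m = pd.DataFrame([[10.0, 10.0, 10.0]], index=["a"], columns=list("xyz"))
        out = row_average_normalize(m, min_overall=0)
        assert out.loc["a"].tolist() == [1.0, 1.0, 1.0]

    def test_sparse_row(self):
        m = pd.DataFrame([[0.0, 0.0, 30.0]], index=["a"], columns=list("xyz"))
        out = row_average_normalize(m, min_overall=0)
        assert out.loc["a"].tolist() == [0.0, 0.0, 3.0]

    def test_row_means_are_one(self, rng):
        m = pd.DataFrame(rng.uniform(0, 100, size=(40, 10)))
        out = row_average_normalize(m, min_overall=20)
        assert np.allclose(out.mean(axis=1), 1.0, atol=1e-12)

    def test_low_expression_rows_dropped(self):
        m = pd.DataFrame(
            [[30.0, 30.0], [5.0, 5.0], [0.0, 0.0]], index=list("abc"), columns=list("xy")
        )
        out = row_average_normalize(m, min_overall=20)
        assert list(out.index) == ["a"]
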