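"""Ratio classifier, localization-based prediction, concordance, rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxoscreen import (
    LocalizationAnnotation,
    classify_hexnac,
    concordance_report,
    load_single_hexnac_annotations,
    load_single_hexnac_benchmark,
    predict_hexnac_from_annotation,
    rank_sum_test,
)
from oxoscreen.classify import (
    CALL_AMBIGUOUS,
    CALL_GALNAC,
    CALL_GLCNAC,
    CALL_NOT_CLASSIFIABLE,
    CALL_UNDEFINED,
)


class TestClassifier:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.19, CALL_GLCNAC),
            (0.3, CALL_GLCNAC),
            (0.44, CALL_AMBIGUOUS),
            (0.5, CALL_AMBIGUOUS),
            (0.6, CALL_GALNAC),
            (0.97, CALL_GALNAC),
            (1.13, CALL_GALNAC),
            (None, CALL_UNDEFINED),
        ],
    )
    def test_default_thresholds(self, ratio, expected):
        assert classify_hexnac(ratio).call == expected

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_hexnac(0.5, low=0.6, high=0.3)
        with pytest.raises(ValueError):
            classify_hexnac(0.5, low=-0.1, high=0.6)

    @given(st.lists(st.floats(min_value=0, max_value=3, allow_nan=False), min_size=2, max_size=30))
    def test_classification_is_monotone_step_function(self, ratios):
        order = {CALL_GLCNAC: 0, CALL_AMBIGUOUS: 1, CALL_GALNAC: 2}
        calls = [order[classify_hexnac(r).call] for r in sorted(ratios)]
        assert calls == sorted(calls)


class TestPrediction:
    @pytest.mark.parametrize(
        "signal,tm,expected",
        [
            (False, False, CALL_GLCNAC),
            (True, False, CALL_GALNAC),
            (False, True, CALL_GALNAC),
            (True, True, CALL_GALNAC),
        ],
    )
    def test_presence_absence_rule(self, signal, tm, expected):
        ann = LocalizationAnnotation("X", signal, tm)
        assert predict_hexnac_from_annotation(ann) == expected


class TestConcordance:
    def test_benchmark_flags_the_published_disagreements(self):
        df = load_single_hexnac_benchmark().merge(
            load_single_hexnac_annotations(), on="accession"
        )
        table, summary = concordance_report(df)
        # annotation-derived predictions reproduce the published ones
        assert (table["predicted"] == df["predicted_hexnac"]).all()
        low = table[table["ratio_144_138"] <= 0.24]
        assert len(low) == 7 and (low["call"] == CALL_GLCNAC).all()
        high = table[table["ratio_144_138"] >= 0.68]
        assert (high["call"] == CALL_GALNAC).all()
        assert summary["discordant_proteins"] == [
            "Nuclear receptor ROR-beta",
            "Protein O-GlcNAcase",
        ]
        assert summary["ambiguous_proteins"] == ["Golgi membrane protein 1"]
        oga = table[table["protein_name"] == "Protein O-GlcNAcase"].iloc[0]
        assert oga["ratio_144_138"] == 1.13
        assert oga["call"] == CALL_GALNAC and oga["predicted"] == CALL_GLCNAC

    def test_all_low_ratio_glcnac_fixture_is_fully_concordant(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "ratio_144_138": [0.1, 0.2, 0.25],
                "signal_peptide": [0, 0, 0],
                "tm_domain": [0, 0, 0],
            }
        )
        table, summary = concordance_report(df)
        assert summary["n_concordant"] == 3 and summary["n_discordant"] == 0

    def test_matches_row_by_row_recomputation(self):
        import pandas as pd

        rng = np.random.default_rng(42)
        ratios = rng.uniform(0, 1.5, size=50)
        signal = rng.integers(0, 2, size=50)
        tm = rng.integers(0, 2, size=50)
        df = pd.DataFrame(
            {"ratio_144_138": ratios, "signal_peptide": signal, "tm_domain": tm}
        )
        table, _ = concordance_report(df)
        for _, row in table.iterrows():
            call = classify_hexnac(row["ratio_144_138"]).call
            pred = CALL_GALNAC if (row["signal_peptide"] or row["tm_domain"]) else CALL_GLCNAC
            assert row["call"] == call and row["predicted"] == pred
            if call in (CALL_GLCNAC, CALL_GALNAC):
                assert row["concordant"] == (call == pred)
            else:
                assert row["concordant"] is None

    def test_multi_hexnac_rows_not_classified(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "ratio_144_138": [0.5],
                "glycan": ["H1N3F1S1"],
                "signal_peptide": [1],
                "tm_domain": [0],
            }
        )
        table, _ = concordance_report(df)
        assert table["call"].iloc[0] == CALL_NOT_CLASSIFIABLE


def _enumeration_pvalue(a, b, alternative="two-sided"):
    """Brute-force exact rank-sum p-value by enumerating all assignments."""
    from scipy.stats import rankdata

    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    n = len(a)
    w_obs = ranks[:n].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n)]
    eps = 1e-9
    p_le = sum(s <= w_obs + eps for s in sums) / len(sums)
    p_ge = sum(s >= w_obs - eps for s in sums) / len(sums)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSum:
    def test_identical_groups_p_one(self):
        a = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = rank_sum_test(a, list(a))
        assert res.method == "exact"
        assert res.p_value == 1.0

    def test_separated_groups_match_enumeration(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 20)

    @pytest.mark.parametrize("na,nb", [(2, 3), (4, 4), (5, 3), (7, 7), (6, 5)])
    def test_exact_agrees_with_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 100 + nb)
        for _ in range(5):
            a = rng.integers(0, 6, size=na).astype(float)  # ties likely
            b = rng.integers(0, 6, size=nb).astype(float)
            for alt in ("two-sided", "greater", "less"):
                got = rank_sum_test(a, b, alternative=alt)
                assert got.method == "exact"
                assert got.p_value == pytest.approx(
                    _enumeration_pvalue(a, b, alt), abs=1e-12
                )

    def test_shift_monotonicity(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5, 5.5]
        p_prev = 1.0
        for shift in (0.0, 1.0, 2.0, 4.0):
            p = rank_sum_test(a, [x + shift for x in b], alternative="less").p_value
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=30)
        b = rng.normal(1, 1, size=30)
        res = rank_sum_test(a, b)
        assert res.method == "normal"
        assert 0 < res.p_value < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
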