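"""Differential expression: FPKM, dispersion, the NB exact test, calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ceranet.de import (
    call_de,
    compute_fpkm,
    de_table,
    estimate_common_dispersion,
    log2_fold_change,
    nb_exact_test,
    relative_expression_ddct,
)
from ceranet.errors import DegenerateInputError, ParameterError


class TestFpkm:
    def test_arithmetic_identity(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 500})
        fpkm = compute_fpkm(counts, lengths, pd.Series({"s1": 1_000_000}))
        assert fpkm.loc["a", "s1"] == 10.0
        assert fpkm.loc["b", "s1"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [7, 13]}, index=["a", "b"])
        lengths = pd.Series({"a": 800, "b": 1200})
        f1 = compute_fpkm(counts, lengths, pd.Series({"s1": 1e6}))
        f2 = compute_fpkm(counts, lengths, pd.Series({"s1": 2e6}))
        assert np.allclose(f2.to_numpy() * 2, f1.to_numpy())

    def test_invalid_parameters(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ParameterError):
            compute_fpkm(counts, pd.Series({"a": 0}), pd.Series({"s1": 1e6}))
        with pytest.raises(ParameterError):
            compute_fpkm(counts, pd.Series({"a": 100}), pd.Series({"s1": 0}))


@pytest.mark.parametrize(
    "a, b, pseudo, expected",
    [(5, 5, 1, 0.0), (10, 20, 1e-9, 1.0), (0, 0, 1, 0.0)],
)
def test_log2_fold_change(a, b, pseudo, expected):
    assert log2_fold_change(a, b, pseudo) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "ddct, expected", [(0.0, 1.0), (-1.0, 2.0), (2.0, 0.25)]
)
def test_relative_expression_ddct(ddct, expected):
    # encode the ddCt in the target/calibrator difference
    assert relative_expression_ddct(ddct, 0.0, 0.0, 0.0) == pytest.approx(expected)


class TestDispersion:
    def test_poisson_truth_near_zero(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(100, size=(2000, 20)))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        assert estimate_common_dispersion(counts, groups) <= 0.02

    def test_nb_truth_recovered(self):
        rng = np.random.default_rng(1)
        phi = 0.2
        lam = rng.gamma(1 / phi, phi * 100, size=(2000, 20))
        counts = pd.DataFrame(rng.poisson(lam))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        est = estimate_common_dispersion(counts, groups)
        assert abs(est - phi) / phi < 0.25

    def test_constant_counts_floor(self):
        counts = pd.DataFrame(np.full((5, 6), 50))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        assert estimate_common_dispersion(counts, groups) == 0.0

    def test_degenerate_inputs(self):
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(DegenerateInputError):
            estimate_common_dispersion(pd.DataFrame(np.zeros((4, 6))), groups)
        with pytest.raises(ParameterError):
            estimate_common_dispersion(
                pd.DataFrame(np.ones((4, 3))), np.array(["a", "a", "b"])
            )


def _oracle_minlike(sum_a, sum_b, n_a, n_b, phi):
    """Independent enumeration of the conditional NB split distribution."""
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    k = np.arange(t + 1)
    if phi == 0:
        pa = stats.poisson.pmf(k, n_a * mu)
        pb = stats.poisson.pmf(t - k, n_b * mu)
    else:
        ra, rb = n_a / phi, n_b / phi
        pa = stats.nbinom.pmf(k, ra, ra / (ra + n_a * mu))
        pb = stats.nbinom.pmf(t - k, rb, rb / (rb + n_b * mu))
    probs = pa * pb
    probs /= probs.sum()
    return min(1.0, probs[probs <= probs[sum_a] * (1 + 1e-7)].sum())


class TestNbExactTest:
    def test_balanced_split_gives_one(self):
        assert nb_exact_test(50, 50, 3, 3, 0.1) == 1.0

    def test_zero_total_convention(self):
        assert nb_exact_test(0, 0, 3, 3, 0.5) == 1.0

    def test_poisson_limit_equals_binomial_minlike(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = int(rng.integers(1, 200))
            a = int(rng.integers(0, t + 1))
            n_a, n_b = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p_binom = _oracle_minlike(a, t - a, n_a, n_b, 0.0)
            assert nb_exact_test(a, t - a, n_a, n_b, 0.0) == pytest.approx(
                p_binom, abs=1e-10
            )

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            t = int(rng.integers(1, 200))
            a = int(rng.integers(0, t + 1))
            n_a, n_b = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            phi = float(rng.choice([0.0, 0.05, 0.2, 1.0]))
            expected = _oracle_minlike(a, t - a, n_a, n_b, phi)
            assert nb_exact_test(a, t - a, n_a, n_b, phi) == pytest.approx(
                expected, abs=1e-12
            )

    @given(
        st.integers(min_value=0, max_value=150),
        st.integers(min_value=0, max_value=150),
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=1, max_value=5),
        st.floats(min_value=0.0, max_value=2.0),
    )
    def test_range_and_group_swap_symmetry(self, a, b, n_a, n_b, phi):
        p = nb_exact_test(a, b, n_a, n_b, phi)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(nb_exact_test(b, a, n_b, n_a, phi), abs=1e-12)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            nb_exact_test(-1, 5, 3, 3, 0.1)
        with pytest.raises(ParameterError):
            nb_exact_test(5, 5, 0, 3, 0.1)
        with pytest.raises(ParameterError):
            nb_exact_test(5, 5, 3, 3, -0.1)


class TestCallDe:
    @pytest.mark.parametrize(
        "p, lfc, significant, direction",
        [
            (0.04, 0.30, True, "up"),
            (0.06, 2.00, False, "up"),
            (0.01, 0.26, True, "up"),   # inclusive boundary by default
            (0.04, -0.30, True, "down"),
            (0.04, 0.20, False, "up"),
        ],
    )
    def test_threshold_rules(self, p, lfc, significant, direction):
        df = pd.DataFrame(
            {"feature_id": ["f"], "log2_fc": [lfc], "p_value": [p]}
        )
        out, counts = call_de(df)
        assert bool(out["significant"].iloc[0]) is significant
        assert out["direction"].iloc[0] == direction
        assert counts["total"] == int(significant)

    def test_strict_boundary_option(self):
        df = pd.DataFrame({"feature_id": ["f"], "log2_fc": [0.26], "p_value": [0.01]})
        out, _ = call_de(df, lfc_strict=True)
        assert not out["significant"].iloc[0]

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1.0),
                st.floats(min_value=-3, max_value=3),
            ),
            max_size=30,
        ),
        st.floats(min_value=0.0, max_value=1.5),
        st.floats(min_value=0.001, max_value=0.2),
    )
    def test_raising_thresholds_never_adds_calls(self, rows, extra_lfc, lower_p):
        df = pd.DataFrame(
            [{"feature_id": f"f{i}", "p_value": p, "log2_fc": l}
             for i, (p, l) in enumerate(rows)],
            columns=["feature_id", "p_value", "log2_fc"],
        )
        base, _ = call_de(df, lfc_threshold=0.26, p_threshold=0.05)
        tighter, _ = call_de(
            df, lfc_threshold=0.26 + extra_lfc, p_threshold=min(0.05, lower_p)
        )
        assert set(tighter.loc[tighter["significant"], "feature_id"]) <= set(
            base.loc[base["significant"], "feature_id"]
        )


class TestDeTable:
    def test_planted_signal_detected_without_false_positives(self, small_dataset):
        table = de_table(
            small_dataset.mrna_counts,
            small_dataset.samples,
            condition_a="laying",
            condition_b="brooding",
        )
        truth = small_dataset.truth.de_truth.set_index("feature_id")
        triad_mrnas = {t.mrna_id for t in small_dataset.triads}
        table = table.set_index("feature_id")
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()
        # direction is the sign of the fold change
        sig = table[table["significant"]]
        assert (
            np.sign(sig["log2_fc"]).map({1.0: "up", -1.0: "down"}) == sig["direction"]
        ).all()
        # background (low-variance) DE mRNAs are all detected
        for fid, row in table.iterrows():
            if truth.loc[fid, "is_de"] and fid not in triad_mrnas:
                assert row["significant"], fid
                assert (row["direction"] == "up") == (truth.loc[fid, "direction"] > 0)
        # no non-DE feature is called
        for fid, row in table.iterrows():
            if not truth.loc[fid, "is_de"]:
                assert not row["significant"], fid

    def test_fpkm_column_sums_scale_with_library_size(self, small_dataset):
        counts = small_dataset.mrna_counts
        lengths = small_dataset.transcript_lengths()
        lib = counts.sum(axis=0)
        fpkm = compute_fpkm(counts, lengths, lib)
        fpkm2 = compute_fpkm(counts, lengths, lib * 2)
        assert np.allclose(fpkm.sum(axis=0), fpkm2.sum(axis=0) * 2)
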