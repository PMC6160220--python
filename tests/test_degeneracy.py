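import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ca1degen.degeneracy import (
    ParameterMatrix,
    bap_attenuation_analysis,
    channel_proportions,
    dunn_test,
    etype_comparison,
    io_curves,
    normalize_parameter_matrix,
    pairwise_spearman,
    spearman_with_p,
    stability_analysis,
)


def matrix_from_columns(cols: dict) -> ParameterMatrix:
    names = list(cols)
    raw = np.column_stack([cols[n] for n in names])
    return ParameterMatrix(etype="test", parameter_names=names, raw=raw)


class TestNormalization:
    def test_divide_by_column_maximum(self):
        m = normalize_parameter_matrix(matrix_from_columns({"a": [2.0, 4.0, 8.0]}))
        assert np.allclose(m.normalized[:, 0], [0.25, 0.5, 1.0])

    def test_constant_column_maps_to_ones(self):
        m = normalize_parameter_matrix(matrix_from_columns({"a": [3.0, 3.0]}))
        assert np.allclose(m.normalized[:, 0], 1.0)

    def test_all_zero_column_flagged_not_divided(self):
        m = normalize_parameter_matrix(
            matrix_from_columns({"a": [0.0, 0.0], "b": [1.0, 2.0]}))
        assert np.allclose(m.column("a"), 0.0)
        assert m.zero_columns == ["a"]

    def test_denormalization_roundtrip(self, rng):
        raw = rng.uniform(0, 5, size=(20, 6))
        m = normalize_parameter_matrix(
            ParameterMatrix("t", [f"p{i}" for i in range(6)], raw))
        assert np.allclose(m.normalized * m.column_max, raw)


class TestStability:
    def test_constant_column_is_stable(self):
        m = matrix_from_columns({"a": [1.0, 1.0, 1.0], "b": [0.1, 0.9, 0.5]})
        assert stability_analysis(normalize_parameter_matrix(m)) == ["a"]

    def test_alternating_column_unstable(self):
        m = matrix_from_columns({"a": [0.0, 1.0, 0.0, 1.0]})
        assert stability_analysis(normalize_parameter_matrix(m)) == []

    def test_uniform_column_sd_matches_analytic_moment(self, rng):
        # sd of U(0,1) = 1/sqrt(12) ~ 0.289 > 0.2
        m = matrix_from_columns({"u": rng.uniform(0, 1, 10_000)})
        norm = normalize_parameter_matrix(m)
        sd = norm.normalized[:, 0].std(ddof=1)
        assert sd == pytest.approx(1 / np.sqrt(12), rel=0.05)
        assert stability_analysis(norm) == []

    def test_recovers_exactly_the_clamped_columns(self, rng):
        """Two tightly-clamped parameters (5% relative sd) among nine loose
        log-uniform ones are exactly the stable set."""
        n = 400
        cols = {}
        for i in range(9):
            cols[f"loose{i}"] = 10 ** rng.uniform(-4, -3, n)
        cols["clamped_a"] = 2e-4 * (1 + 0.05 * rng.standard_normal(n))
        cols["clamped_b"] = 7e-3 * (1 + 0.05 * rng.standard_normal(n))
        stable = stability_analysis(normalize_parameter_matrix(matrix_from_columns(cols)))
        assert sorted(stable) == ["clamped_a", "clamped_b"]


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        x = np.arange(10.0)
        m = matrix_from_columns({"x": x, "y": 2 * x, "z": -x})
        table = pairwise_spearman(normalize_parameter_matrix(m), reduce=False)
        t = table.set_index(["param_a", "param_b"])
        assert t.loc[("x", "y"), "rho"] == pytest.approx(1.0)
        assert t.loc[("x", "z"), "rho"] == pytest.approx(-1.0)
        assert t.loc[("x", "y"), "flagged"] and t.loc[("x", "z"), "flagged"]

    def test_tie_corrected_rho_matches_rank_then_pearson(self, rng):
        """8-point vectors with ties equal a brute-force rank + Pearson."""
        for _ in range(20):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 4, 8).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rho, _ = spearman_with_p(x, y)
            brute = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(brute, rel=1e-12)

    def test_exact_permutation_p_small_n(self, rng):
        """Exact p equals full enumeration over all rank permutations."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman_with_p(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        count = sum(
            abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho) - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(count / math.factorial(6))

    def test_constant_column_reported_unflagged(self):
        m = matrix_from_columns({"c": [1.0] * 6, "x": np.arange(6.0)})
        table = pairwise_spearman(normalize_parameter_matrix(m), reduce=False)
        assert np.isnan(table.iloc[0]["rho"]) and not table.iloc[0]["flagged"]

    def test_reduction_keeps_only_flagged_parameters(self, rng):
        x = np.arange(10.0)
        m = matrix_from_columns({
            "x": x, "y": x + 0.01 * rng.standard_normal(10),
            "noise1": rng.standard_normal(10), "noise2": rng.standard_normal(10),
        })
        table = pairwise_spearman(normalize_parameter_matrix(m), reduce=True)
        names = set(table.param_a) | set(table.param_b)
        assert names == {"x", "y"}


class TestProportions:
    def test_two_channel_fractions(self):
        m = matrix_from_columns({"gxbar s": [3.0, 3.0], "gybar s": [1.0, 1.0]})
        t = channel_proportions(m)
        assert dict(zip(t.parameter, t.fraction)) == pytest.approx(
            {"gxbar s": 0.75, "gybar s": 0.25})

    def test_single_channel_is_unity(self):
        t = channel_proportions(matrix_from_columns({"gxbar s": [0.5, 1.5]}))
        assert t.fraction.iloc[0] == 1.0

    def test_fractions_sum_to_one_and_match_two_pass(self, rng):
        cols = {f"g{c}bar s": rng.uniform(0, 1e-2, 40)
                for c in ("na", "kdr", "ka", "km", "kd", "can", "cal", "cat",
                          "ih", "kca", "cagk")}
        t = channel_proportions(matrix_from_columns(cols))
        assert t.fraction.sum() == pytest.approx(1.0, abs=1e-12)
        means = {k: np.mean(v) for k, v in cols.items()}  # independent pass
        total = sum(means.values())
        for _, row in t.iterrows():
            assert row.fraction == pytest.approx(means[row.parameter] / total)

    def test_all_zero_means_error(self):
        with pytest.raises(ValueError):
            channel_proportions(matrix_from_columns({"gxbar s": [0.0, 0.0]}))


class TestEtypeComparison:
    def test_identical_groups_no_flags(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        samples = {e: {"p": vals.copy()} for e in ("a", "b", "c", "d")}
        assert etype_comparison(samples).empty

    def test_permuted_groups_not_flagged(self, rng):
        vals = rng.normal(0, 1, 12)
        samples = {"a": {"p": vals}, "b": {"p": rng.permutation(vals)}}
        assert etype_comparison(samples).empty

    def test_shifted_groups_flagged_with_direction(self, rng):
        samples = {
            "low": {"p": rng.normal(0.0, 0.1, 20)},
            "high": {"p": rng.normal(5.0, 0.1, 20)},
        }
        table = etype_comparison(samples)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.direction == "lower" and row.p < 0.05

    def test_dunn_pairwise_structure(self, rng):
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(0, 1, 15),
            "c": rng.normal(8, 1, 15),
        }
        t = dunn_test(groups)
        assert len(t) == 3  # all pairs
        flagged = t[t.flagged]
        assert set(map(tuple, flagged[["group_a", "group_b"]].values)) == {
            ("a", "c"), ("b", "c")}


class TestIOCurves:
    def test_identical_distributions_similar(self):
        counts = {0.4: np.array([4, 5, 6, 5])}
        t = io_curves(counts, {0.4: np.array([4, 5, 6, 5])})
        row = t.iloc[0]
        assert row.model_mean == row.reference_mean
        assert not row.different

    def test_shifted_distributions_detected(self):
        t = io_curves({0.4: np.array([4, 5, 6])}, {0.4: np.array([10, 11, 12])})
        row = t.iloc[0]
        assert row.model_mean < row.reference_mean
        # exact two-sided U p for fully separated 3x3 samples
        assert row.p == pytest.approx(0.1, rel=1e-6)
        U, p = stats.mannwhitneyu([4, 5, 6], [10, 11, 12], alternative="two-sided")
        assert row.p == pytest.approx(p)

    def test_small_samples_skipped_with_note(self):
        with pytest.warns(UserWarning, match="test skipped"):
            t = io_curves({0.4: np.array([4, 5])}, {0.4: np.array([5, 6, 7])})
        assert not t.iloc[0].tested


class TestBapClassification:
    def test_strong_attenuation(self):
        prof = [(0.0, 100.0), (100.0, 60.0), (200.0, 20.0)]
        assert bap_attenuation_analysis(prof)["class"] == "strong-attenuating"

    def test_weak_attenuation(self):
        prof = [(0.0, 100.0), (100.0, 80.0), (200.0, 55.0)]
        assert bap_attenuation_analysis(prof)["class"] == "weak-attenuating"

    def test_intermediate_boundary(self):
        prof = [(0.0, 100.0), (100.0, 70.0), (200.0, 40.0)]
        assert bap_attenuation_analysis(prof)["class"] == "intermediate"

    def test_requires_distal_coverage(self):
        with pytest.raises(ValueError):
            bap_attenuation_analysis([(0.0, 100.0), (50.0, 80.0), (120.0, 60.0)])


def test_imposed_inverse_km_cagk_coupling_recovered():
    """A population generated with a strong inverse coupling between the
    M-type and BK conductances is flagged with negative rho."""
    from ca1degen.synthetic import make_ground_truth

    pop = make_ground_truth("pyr_cAC_desk", n=100, seed=4)
    mat = normalize_parameter_matrix(
        ParameterMatrix("pyr_cAC_desk", pop.param_names, pop.vectors))
    table = pairwise_spearman(mat, reduce=False)
    row = table[(table.param_a == "gkmbar s") & (table.param_b == "gcagkbar s")]
    if row.empty:
        row = table[(table.param_b == "gkmbar s") & (table.param_a == "gcagkbar s")]
    r = row.iloc[0]
    assert r.rho < -0.25 and r.p < 0.05 and r.flagged
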