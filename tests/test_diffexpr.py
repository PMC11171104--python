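import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_counts
from mmint import diffexpr as de
from mmint import synthetic_data as sd
from mmint.exceptions import InsufficientDataError, NormalizationError, ValidationError
from oracles import bh_adjust


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_counts(np.tile([[10], [20], [30], [5]], (1, 4)), 2, 2)
        sf = de.size_factors(cm)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_hand_computation(self):
        # sample 2 = 2 x sample 1 over 5 features: after rescaling to
        # geometric mean 1 the factors are (1/sqrt(2), sqrt(2))
        base = np.array([10, 20, 30, 40, 50])
        arr = np.column_stack([base, 2 * base, base, 2 * base])
        cm = make_counts(arr, 2, 2)
        sf = de.size_factors(cm)
        assert np.allclose(sf, [2**-0.5, 2**0.5, 2**-0.5, 2**0.5])

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(1, 1000, size=(30, 4))
        cm = make_counts(arr, 2, 2)
        perm = rng.permutation(30)
        cm_perm = make_counts(arr[perm], 2, 2, feature_ids=[f"f{i}" for i in perm])
        assert np.allclose(de.size_factors(cm), de.size_factors(cm_perm))

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.integers(1, 500, size=(50, 6)), 3, 3)
        sf = de.size_factors(cm)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-9)

    def test_no_all_positive_feature_raises(self):
        arr = np.array([[0, 5, 5, 5], [5, 0, 5, 5]])
        with pytest.raises(NormalizationError):
            de.size_factors(make_counts(arr, 2, 2))

    def test_scaling_one_column_scales_its_factor(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(1, 500, size=(40, 4))
        sf0 = de.size_factors(make_counts(arr, 2, 2))
        arr2 = arr.copy()
        arr2[:, 0] *= 3
        sf1 = de.size_factors(make_counts(arr2, 2, 2))
        # ratio to the global rescale: column 0's factor grew by 3
        rel = (sf1 / sf0).to_numpy()
        assert np.allclose(rel[0] / rel[1], 3.0)
        assert np.allclose(rel[1:], rel[1])


class TestDispersion:
    def test_constant_counts_floor(self):
        cm = make_counts(np.full((3, 6), 100), 3, 3)
        sf = de.size_factors(cm)
        alpha = de.estimate_dispersion(cm, sf)
        assert (alpha == de.ALPHA_FLOOR).all()

    def test_recovery_of_true_dispersion(self):
        truth = sd.generate_ground_truth(2, 2000, 0, 1.0, seed=7, dispersion=0.1)
        _, mrna = sd.simulate_counts(truth, n_rep=10, seed=8)
        sf = de.size_factors(mrna)
        alpha = de.estimate_dispersion(mrna, sf)
        assert 0.05 <= float(np.median(alpha)) <= 0.2

    def test_floor_invariant(self):
        rng = np.random.default_rng(3)
        cm = make_counts(rng.integers(1, 50, size=(100, 6)), 3, 3)
        alpha = de.estimate_dispersion(cm, de.size_factors(cm))
        assert (alpha >= de.ALPHA_FLOOR).all()


class TestWaldTest:
    def test_all_zero_feature_degenerate(self):
        arr = np.array([[0, 0, 0, 0, 0, 0], [100, 90, 110, 100, 95, 105]])
        cm = make_counts(arr, 3, 3)
        sf = de.size_factors(cm)
        alpha = de.estimate_dispersion(cm, sf)
        res = de.nb_wald_test(cm, sf, alpha)
        assert res.loc["f0", "log2fc"] == 0.0
        assert res.loc["f0", "pvalue"] == 1.0

    def test_null_type_one_error_calibration(self):
        truth = sd.generate_ground_truth(2, 2000, 0, 1.0, seed=11, dispersion=0.1)
        _, mrna = sd.simulate_counts(truth, n_rep=3, seed=12)
        res = de.de_results(mrna)
        assert 0.03 <= float((res["pvalue"] < 0.05).mean()) <= 0.07

    def test_planted_effect_recovery(self):
        # planted |log2FC| = 2 at base mean 500: estimates centre on 2
        truth = sd.generate_ground_truth(
            50, 2000, 200, 2.0, seed=13,
            base_mean_range=(500.0, 500.0), dispersion=0.05,
        )
        _, mrna = sd.simulate_counts(truth, n_rep=3, seed=14)
        res = de.de_results(mrna).set_index("feature_id")
        planted_up = [g for g, l in truth.gene_lfc.items() if l == 2.0]
        assert abs(float(res.loc[planted_up, "log2fc"].median()) - 2.0) <= 0.3

    def test_swapping_conditions_negates_lfc_keeps_pvalues(self):
        rng = np.random.default_rng(15)
        arr = rng.poisson(200, size=(50, 6))
        cm = make_counts(arr, 3, 3)
        swapped_cond = {
            s: ("treated" if c == "control" else "control") for s, c in cm.condition.items()
        }
        cm_sw = make_counts(arr, 3, 3)
        cm_sw.condition = swapped_cond
        sf = de.size_factors(cm)
        alpha = de.estimate_dispersion(cm, sf)
        a = de.nb_wald_test(cm, sf, alpha)
        b = de.nb_wald_test(cm_sw, sf, de.estimate_dispersion(cm_sw, sf))
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["pvalue"], b["pvalue"])

    def test_column_scaling_leaves_lfc_unchanged(self):
        # without the pseudo-count the fold change is exactly invariant to
        # rescaling one sample's library
        rng = np.random.default_rng(16)
        arr = rng.poisson(300, size=(40, 6)) + 1
        cm = make_counts(arr, 3, 3)
        arr2 = arr.copy()
        arr2[:, 2] *= 5
        cm2 = make_counts(arr2, 3, 3)
        a = de.nb_wald_test(cm, de.size_factors(cm), de.estimate_dispersion(cm, de.size_factors(cm)), pseudo_count=0.0)
        b = de.nb_wald_test(cm2, de.size_factors(cm2), de.estimate_dispersion(cm2, de.size_factors(cm2)), pseudo_count=0.0)
        assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-10)


class TestAdjustAndFilter:
    def test_single_pvalue_unchanged(self):
        assert de.adjust_pvalues([0.04])[0] == pytest.approx(0.04)

    def test_bh_hand_example(self):
        adj = de.adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            de.adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_bh_matches_definition(self, pvals):
        assert np.allclose(de.adjust_pvalues(pvals), bh_adjust(pvals))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20))
    def test_bh_preserves_order(self, pvals):
        adj = de.adjust_pvalues(pvals)
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def _record(self, count, padj, lfc, fid="x"):
        return {
            "feature_id": fid, "base_mean": 100.0, "log2fc": lfc, "pvalue": padj,
            "padj": padj, "total_raw_count": count, "rpm_control": 10.0,
            "rpm_treated": 10.0, "direction": "ns",
        }

    def test_filter_boundaries(self):
        recs = pd.DataFrame([
            self._record(49, 0.001, 3.0, "below_count"),
            self._record(50, 0.05, 1.0, "at_boundaries"),
            self._record(50, 0.05, -1.0, "down_boundary"),
            self._record(50, 0.051, 2.0, "padj_fail"),
            self._record(50, 0.05, 0.999, "lfc_fail"),
        ])
        up, down = de.filter_de(recs)
        assert list(up["feature_id"]) == ["at_boundaries"]
        assert list(down["feature_id"]) == ["down_boundary"]

    def test_filter_toy_table(self):
        # 10 records designed so exactly 3 survive the three predicates
        rows = [
            self._record(500, 0.01, 2.0, "s1"),
            self._record(60, 0.04, -1.5, "s2"),
            self._record(50, 0.05, 1.0, "s3"),
            self._record(49, 0.01, 2.0, "f1"),
            self._record(10, 0.001, 5.0, "f2"),
            self._record(500, 0.06, 2.0, "f3"),
            self._record(500, 0.5, -3.0, "f4"),
            self._record(500, 0.01, 0.5, "f5"),
            self._record(500, 0.01, -0.99, "f6"),
            self._record(500, 1.0, 0.0, "f7"),
        ]
        up, down = de.filter_de(pd.DataFrame(rows))
        assert set(up["feature_id"]) == {"s1", "s3"}
        assert set(down["feature_id"]) == {"s2"}


class TestRPMFilter:
    def _matrix(self, rows):
        # pad a filler feature so every column sums to 1e6: RPM == count
        arr = np.array(rows, dtype=np.int64)
        filler = 1_000_000 - arr.sum(axis=0)
        return make_counts(
            np.vstack([arr, filler]), 2, 2,
            feature_ids=[f"f{i}" for i in range(len(rows))] + ["filler"],
        )

    def test_inclusive_boundary_kept(self):
        cm = self._matrix([[6, 6, 6, 6]])
        assert "f0" in de.rpm_filter(cm, 6.0)

    def test_either_condition_failing_excludes(self):
        cm = self._matrix([[100, 100, 5, 6]])  # treated mean 5.5 < 6
        assert "f0" not in de.rpm_filter(cm, 6.0)

    def test_hand_computed_kept_set(self):
        cm = self._matrix([
            [6, 6, 6, 6],        # kept at 6
            [100, 100, 5, 6],    # treated mean 5.5 -> dropped
            [7, 5, 6, 6],        # control mean 6 -> kept
            [0, 0, 20, 20],      # control mean 0 -> dropped
        ])
        assert de.rpm_filter(cm, 6.0) == {"f0", "f2", "filler"}

    def test_threshold_12_is_stricter(self):
        cm = self._matrix([[6, 6, 6, 6], [12, 12, 12, 12]])
        assert de.rpm_filter(cm, 12.0) == {"f1", "filler"}


class TestConcordance:
    def test_perfect_and_inverse_correlation(self):
        a = {"x": 1.0, "y": 2.0, "z": -1.0}
        assert de.concordance(a, a) == pytest.approx(1.0)
        assert de.concordance(a, {k: -v for k, v in a.items()}) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        a = dict(zip("abcde", [0.0, 1.0, 2.0, 3.0, 4.0]))
        b = dict(zip("abcde", [1.0, 0.0, 2.0, 4.0, 3.0]))
        assert de.concordance(a, b) == pytest.approx(0.8)

    def test_too_few_shared_features(self):
        with pytest.raises(InsufficientDataError):
            de.concordance({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def test_null_chain_empirical_fdr_is_controlled():
    """With no planted effects the full filter chain reports (almost) nothing."""
    truth = sd.generate_ground_truth(2, 2000, 0, 1.0, seed=17, dispersion=0.1)
    _, mrna = sd.simulate_counts(truth, n_rep=3, seed=18)
    res = de.de_results(mrna)
    up, down = de.filter_de(res)
    n_disc = len(up) + len(down)
    assert n_disc / max(len(res), 1) <= 0.10
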