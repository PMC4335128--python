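"""Substructure attribution: predictive (count-zeroing) and Student's methods."""

import numpy as np
import pandas as pd
import pytest

from pcmlearn.bioactivity import BioactivityTable
from pcmlearn.interpretation import (
    classify_substructures,
    predictive_contribution,
    predictive_contribution_map,
    students_method,
    students_method_map,
)
from pcmlearn.pcm import PCMRegressor


class _LinearOracle:
    """Predicts a fixed linear function of raw counts (no preprocessing)."""

    def __init__(self, coefficients: dict[str, float]):
        self.coefficients = coefficients

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for col, coef in self.coefficients.items():
            out += coef * X[col].to_numpy(dtype=float)
        return out


class TestPredictiveContribution:
    def test_linear_oracle_unit_counts_recover_coefficient(self):
        X = pd.DataFrame({"s1": [1.0, 1.0, 0.0, 1.0], "s2": [0.0, 2.0, 1.0, 3.0]})
        oracle = _LinearOracle({"s1": 2.0, "s2": -0.5})
        contribution = predictive_contribution(oracle, X, "s1")
        assert contribution.mean_delta == pytest.approx(2.0)
        assert contribution.sd_delta == pytest.approx(0.0)
        assert contribution.n_compounds == 3

    def test_zero_coefficient_gives_zero_delta(self):
        X = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 0.0]})
        oracle = _LinearOracle({"s2": 3.0})
        assert predictive_contribution(oracle, X, "s1").mean_delta == pytest.approx(0.0)

    def test_count_weighted_mean(self):
        # counts 1 and 3 with unit coefficient: (1*1 + 3*3) / 4 = 2.5
        X = pd.DataFrame({"s1": [1.0, 3.0]})
        oracle = _LinearOracle({"s1": 1.0})
        contribution = predictive_contribution(oracle, X, "s1")
        assert contribution.mean_delta == pytest.approx(2.5)
        assert contribution.total_count == 4.0

    def test_absent_substructure_raises(self):
        X = pd.DataFrame({"s1": [0.0, 0.0]})
        with pytest.raises(ValueError):
            predictive_contribution(_LinearOracle({"s1": 1.0}), X, "s1")

    def test_zeroing_is_local_to_the_column(self):
        """Zeroing one substructure must not disturb other columns."""
        X = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]})
        seen = []

        class Probe:
            def predict(self, rows):
                seen.append(rows.copy())
                return np.zeros(len(rows))

        predictive_contribution(Probe(), X, "s1")
        original, zeroed = seen
        assert np.array_equal(original["s2"], zeroed["s2"])
        assert np.array_equal(zeroed["s1"], [0.0, 0.0])
        assert np.array_equal(X["s1"], [1.0, 2.0])  # caller's frame untouched

    def test_zeroing_happens_before_frozen_scaling(self):
        """With a fitted pipeline, raw-count zeroing passes through the same
        frozen center/scale transform as the original rows."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"s1": rng.integers(0, 3, 200).astype(float),
             "s2": rng.integers(0, 4, 200).astype(float)}
        )
        y = 6.0 + 1.5 * X["s1"].to_numpy() - 0.5 * X["s2"].to_numpy()
        model = PCMRegressor(nzv_cutoff=None, scale=True).fit(X, y)
        unit_rows = X[X["s1"] == 1]
        contribution = predictive_contribution(model, unit_rows, "s1")
        assert contribution.mean_delta == pytest.approx(1.5, abs=1e-8)


class TestContributionMap:
    def test_one_entry_per_occurring_substructure(self):
        X = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 0.0], "s3": [2.0, 1.0]})
        oracle = _LinearOracle({"s1": 1.0, "s2": 1.0, "s3": -2.0})
        contributions = predictive_contribution_map(oracle, X, ["s1", "s2", "s3"])
        assert [c.substructure_id for c in contributions] == ["s3", "s1"]

    def test_ordering_by_magnitude_then_id(self):
        X = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]})
        oracle = _LinearOracle({"a": -1.0, "b": 1.0, "c": 2.0})
        contributions = predictive_contribution_map(oracle, X, ["a", "b", "c"])
        assert [c.substructure_id for c in contributions] == ["c", "a", "b"]

    def test_target_restriction_on_pair_indexed_design(self):
        index = pd.MultiIndex.from_tuples(
            [("c1", "t1"), ("c2", "t1"), ("c1", "t2")],
            names=["compound_id", "target_id"],
        )
        X = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=index)
        oracle = _LinearOracle({"s1": 1.0})
        contributions = predictive_contribution_map(oracle, X, ["s1"], target_id="t1")
        assert contributions[0].n_compounds == 2
        with pytest.raises(KeyError):
            predictive_contribution_map(oracle, X, ["s1"], target_id="t9")

    def test_deterministic_rerun(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 0.0]})
        oracle = _LinearOracle({"a": 1.0, "b": 1.0})
        first = predictive_contribution_map(oracle, X, ["a", "b"])
        second = predictive_contribution_map(oracle, X, ["a", "b"])
        assert [c.substructure_id for c in first] == [c.substructure_id for c in second]


def _table_from_values(values: dict[str, float], target: str = "T1") -> BioactivityTable:
    entries = {(cid, target): v for cid, v in values.items()}
    return BioactivityTable(entries=entries, n_source_records={k: 1 for k in entries})


class TestStudentsMethod:
    @staticmethod
    def _gaussian_groups(mean_a, mean_b, n=50, seed=0):
        rng = np.random.default_rng(seed)
        values = {}
        counts = {}
        for i in range(n):
            values[f"p{i}"] = rng.normal(mean_a, 0.5)
            counts[f"p{i}"] = 1.0
        for i in range(n):
            values[f"a{i}"] = rng.normal(mean_b, 0.5)
            counts[f"a{i}"] = 0.0
        table = _table_from_values(values)
        count_frame = pd.DataFrame({"s1": pd.Series(counts)})
        return table, count_frame

    def test_same_distribution_not_significant(self):
        table, counts = self._gaussian_groups(6.0, 6.0, seed=1)
        result = students_method(table, counts, "s1", "T1")
        assert result.assessed
        assert result.label == "not significant"

    def test_shifted_distribution_beneficial(self):
        table, counts = self._gaussian_groups(7.0, 6.0, seed=2)
        result = students_method(table, counts, "s1", "T1")
        assert result.label == "beneficial"
        assert result.mean_difference == pytest.approx(1.0, abs=0.3)
        assert result.t_p < 0.05

    def test_downshifted_distribution_deleterious(self):
        table, counts = self._gaussian_groups(5.0, 6.0, seed=3)
        assert students_method(table, counts, "s1", "T1").label == "deleterious"

    def test_small_group_not_assessed(self):
        values = {"p1": 6.0, "p2": 6.5, "a1": 6.1, "a2": 6.2, "a3": 6.3}
        counts = pd.DataFrame(
            {"s1": pd.Series({"p1": 1.0, "p2": 1.0, "a1": 0.0, "a2": 0.0, "a3": 0.0})}
        )
        result = students_method(_table_from_values(values), counts, "s1", "T1")
        assert not result.assessed
        assert result.label == "not assessed"

    def test_normality_gate_blocks_t_test(self):
        rng = np.random.default_rng(4)
        values = {}
        counts = {}
        for i in range(60):  # present group strongly bimodal
            values[f"p{i}"] = 4.0 if i % 2 else 9.0
            counts[f"p{i}"] = 1.0
        for i in range(60):
            values[f"a{i}"] = rng.normal(6, 0.5)
            counts[f"a{i}"] = 0.0
        result = students_method(
            _table_from_values(values), pd.DataFrame({"s1": pd.Series(counts)}), "s1", "T1"
        )
        assert not result.assessed
        assert result.t_p is None
        assert result.shapiro_p_present < 0.05

    def test_unknown_target_raises(self):
        table, counts = self._gaussian_groups(6.0, 6.0)
        with pytest.raises(KeyError):
            students_method(table, counts, "s1", "T9")

    def test_invariant_to_compound_ordering(self):
        table, counts = self._gaussian_groups(7.0, 6.0, seed=5)
        shuffled = counts.sample(frac=1.0, random_state=0)
        a = students_method(table, counts, "s1", "T1")
        b = students_method(table, shuffled, "s1", "T1")
        assert a.label == b.label and a.t_p == pytest.approx(b.t_p)


class TestClassify:
    @staticmethod
    def _result(sub, label, target, diff=1.0):
        from pcmlearn.interpretation import StudentResult

        return StudentResult(
            substructure_id=sub, bioactivity_set=target, n_present=50, n_absent=50,
            shapiro_p_present=0.5, shapiro_p_absent=0.5,
            t_p=0.01 if label in ("beneficial", "deleterious") else 0.5,
            mean_difference=diff if label != "deleterious" else -diff,
            assessed=True, label=label,
        )

    def test_six_bins(self):
        set1 = [
            self._result("a", "beneficial", "COX1"),
            self._result("b", "not significant", "COX1"),
            self._result("c", "beneficial", "COX1"),
            self._result("d", "deleterious", "COX1"),
        ]
        set2 = [
            self._result("a", "not significant", "COX2"),
            self._result("b", "beneficial", "COX2"),
            self._result("c", "beneficial", "COX2"),
            self._result("d", "beneficial", "COX2"),
        ]
        frame = classify_substructures(set1, set2)
        assert frame.loc["a", "bin"] == "increase on COX1 only"
        assert frame.loc["b", "bin"] == "increase on COX2 only"
        assert frame.loc["c", "bin"] == "increase on both"
        assert frame.loc["d", "bin"] == "opposite"

    def test_mismatched_vocabularies_raise(self):
        with pytest.raises(ValueError):
            classify_substructures(
                [self._result("a", "beneficial", "COX1")],
                [self._result("b", "beneficial", "COX2")],
            )

    def test_volcano_columns_present(self):
        frame = classify_substructures(
            [self._result("a", "beneficial", "COX1")],
            [self._result("a", "deleterious", "COX2")],
        )
        for col in ("mean_diff_set1", "neglog10_p_set2", "n_present_set1"):
            assert col in frame.columns


class TestMethodDisagreement:
    def test_constructed_scenario_splits_the_methods(self):
        """A passenger substructure co-occurring with the driver: the
        model-based method calls it inert while the distribution comparison
        calls it beneficial."""
        from pcmlearn.synthetic import method_disagreement_scenario

        table, counts = method_disagreement_scenario(seed=0)
        y = np.array([table.entries[(cid, "T1")] for cid in counts.index])
        model = PCMRegressor(nzv_cutoff=None, scale=False).fit(counts, y)

        predictive = predictive_contribution(model, counts, "S1")
        student = students_method(table, counts, "S1", "T1")
        assert abs(predictive.mean_delta) < 0.2
        assert student.label == "beneficial"
        # and the driver substructure is recognized by both
        driver = predictive_contribution(model, counts, "S2")
        assert driver.mean_delta == pytest.approx(0.8, abs=0.25)


class TestStudentsMap:
    def test_bh_adjustment_only_relabels_assessed(self):
        rng = np.random.default_rng(0)
        values = {}
        counts = {"s1": {}, "s2": {}}
        for i in range(60):
            cid = f"c{i}"
            s1 = float(i < 30)
            values[cid] = rng.normal(6 + s1, 0.4)
            counts["s1"][cid] = s1
            counts["s2"][cid] = float(i % 2)
        table = _table_from_values(values)
        frame = pd.DataFrame({k: pd.Series(v) for k, v in counts.items()})
        plain = students_method_map(table, frame, "T1")
        adjusted = students_method_map(table, frame, "T1", adjust="bh")
        assert [r.substructure_id for r in plain] == [r.substructure_id for r in adjusted]
        by_id = {r.substructure_id: r for r in adjusted}
        assert by_id["s1"].label == "beneficial"
        assert by_id["s1"].t_p >= {r.substructure_id: r for r in plain}["s1"].t_p
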