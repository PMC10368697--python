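"""Metric machinery vs independent direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skelpatch.evaluate import (
    ConfusionCounts,
    confusion_from_patches,
    dsc,
    metric_panel,
    seg_scores,
    stratified_report,
    stratum_of,
)


class TestConfusion:
    def test_all_correct(self):
        c = confusion_from_patches([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (2, 2)

    def test_all_false_positive(self):
        c = confusion_from_patches([1] * 5, [0] * 5)
        assert (c.tp, c.tn, c.fn, c.fp) == (0, 0, 0, 5)

    def test_random_set_matches_loop_oracle(self, rng):
        preds = rng.integers(0, 2, 200)
        labs = rng.integers(0, 2, 200)
        c = confusion_from_patches(preds, labs)
        # independent pairwise loop
        tp = sum(1 for p, l in zip(preds, labs) if p == 1 and l == 1)
        fp = sum(1 for p, l in zip(preds, labs) if p == 1 and l == 0)
        fn = sum(1 for p, l in zip(preds, labs) if p == 0 and l == 1)
        tn = sum(1 for p, l in zip(preds, labs) if p == 0 and l == 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_from_patches([], [])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestPanel:
    def test_perfect_classifier(self):
        panel = metric_panel(ConfusionCounts(tp=1, tn=1))
        assert all(v == 1.0 for v in panel.values())

    def test_ppv_direct_substitution(self):
        panel = metric_panel(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        assert panel["ppv"] == 0.75

    def test_fuzzed_counts_match_formula_oracle(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, 4))
            c = ConfusionCounts(tp, fp, tn, fn)
            if c.total == 0:
                continue
            panel = metric_panel(c)
            oracle = {
                "accuracy": (tp + tn) / (tp + fp + tn + fn),
                "sensitivity": tp / (tp + fn) if tp + fn else None,
                "specificity": tn / (tn + fp) if tn + fp else None,
                "ppv": tp / (tp + fp) if tp + fp else None,
                "npv": tn / (tn + fn) if tn + fn else None,
            }
            for k, v in oracle.items():
                if v is None:
                    assert panel[k] is None
                else:
                    assert abs(panel[k] - v) < 1e-12

    def test_undefined_reported_as_none_not_zero(self):
        panel = metric_panel(ConfusionCounts(tn=5))
        assert panel["sensitivity"] is None
        assert panel["ppv"] is None
        assert panel["specificity"] == 1.0

    def test_percent_formatting(self):
        panel = metric_panel(ConfusionCounts(tp=3, fp=1, tn=4, fn=2), as_percent=True)
        assert panel["ppv"] == 75.0

    def test_accuracy_is_prevalence_weighted_mean(self, rng):
        """accuracy = prev*sens + (1-prev)*spec, hence between the two."""
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, 4))
            panel = metric_panel(ConfusionCounts(tp, fp, tn, fn))
            prev = (tp + fn) / (tp + fp + tn + fn)
            recon = prev * panel["sensitivity"] + (1 - prev) * panel["specificity"]
            assert abs(panel["accuracy"] - recon) < 1e-12


@settings(deadline=None, derandomize=True, max_examples=80)
@given(st.tuples(*[st.integers(0, 10**6)] * 4))
def test_panel_identities_hold_for_any_counts(counts):
    """For arbitrary confusion counts: defined metrics lie in [0,1], and
    accuracy equals the prevalence-weighted mean of sensitivity and
    specificity whenever both are defined."""
    tp, fp, tn, fn = counts
    c = ConfusionCounts(tp, fp, tn, fn)
    if c.total == 0:
        return
    panel = metric_panel(c)
    for v in panel.values():
        assert v is None or 0.0 <= v <= 1.0
    if panel["sensitivity"] is not None and panel["specificity"] is not None:
        prev = (tp + fn) / c.total
        recon = prev * panel["sensitivity"] + (1 - prev) * panel["specificity"]
        assert abs(panel["accuracy"] - recon) < 1e-9


class TestDSC:
    def test_identical_masks(self, rng):
        m = rng.uniform(0, 1, (10, 10, 10)) > 0.5
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0, 0, 0] = b[5, 5, 5] = True
        assert dsc(a, b) == 0.0

    def test_half_overlap_cube(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0:2, 0:2, 0:2] = True  # 8 voxels
        b[0:2, 0:2, 1:3] = True  # 8 voxels, 4 shared
        assert dsc(a, b) == 0.5

    def test_symmetry_on_fuzzed_masks(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 1, (7, 7, 7)) > 0.6
            b = rng.uniform(0, 1, (7, 7, 7)) > 0.6
            if not (a.any() or b.any()):
                continue
            assert dsc(a, b) == dsc(b, a)
            assert 0.0 <= dsc(a, b) <= 1.0

    def test_fuzzed_masks_match_set_arithmetic_oracle(self, rng):
        for _ in range(100):
            a = rng.uniform(0, 1, (6, 6, 6)) > rng.uniform(0.3, 0.9)
            b = rng.uniform(0, 1, (6, 6, 6)) > rng.uniform(0.3, 0.9)
            if not (a.any() or b.any()):
                continue
            sa = {tuple(i) for i in np.argwhere(a)}
            sb = {tuple(i) for i in np.argwhere(b)}
            oracle = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert abs(dsc(a, b) - oracle) < 1e-12

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            dsc(np.ones((4, 4, 4), bool), np.ones((5, 5, 5), bool))

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            dsc(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool))


class TestSegScores:
    def test_both_empty_cases_excluded(self, rng):
        m = rng.uniform(0, 1, (5, 5, 5)) > 0.5
        empty = np.zeros((5, 5, 5), bool)
        s = seg_scores([("a", m, m), ("b", empty, empty)])
        assert s.per_case_dsc == [1.0]
        assert s.n_excluded == 1

    def test_mean_between_min_max(self, rng):
        cases = []
        for i in range(5):
            g = rng.uniform(0, 1, (6, 6, 6)) > 0.5
            p = rng.uniform(0, 1, (6, 6, 6)) > 0.5
            cases.append((str(i), g, p))
        s = seg_scores(cases)
        assert min(s.per_case_dsc) <= s.mean_dsc <= max(s.per_case_dsc)


class TestStrata:
    def test_one_case_per_stratum(self):
        df = pd.DataFrame({"case_id": ["a", "b", "c"], "dsc": [0.5, 0.6, 0.7]})
        rep = stratified_report(df, {"a": 2.0, "b": 7.0, "c": 15.0})
        assert rep["n_cases"].tolist() == [1, 1, 1]
        assert rep["dsc"].tolist() == [0.5, 0.6, 0.7]

    def test_empty_strata_reported_empty_not_zero(self):
        df = pd.DataFrame({"case_id": ["a", "b"], "dsc": [0.4, 0.8]})
        rep = stratified_report(df, {"a": 2.0, "b": 3.0})
        assert rep.loc[rep.stratum == "5-10 mm", "n_cases"].item() == 0
        assert np.isnan(rep.loc[rep.stratum == "5-10 mm", "dsc"].item())

    def test_means_match_groupby_oracle(self, rng):
        ids = [f"c{i}" for i in range(12)]
        dscs = rng.uniform(0, 1, 12)
        diam = {c: float(rng.uniform(1.8, 20)) for c in ids}
        df = pd.DataFrame({"case_id": ids, "dsc": dscs})
        rep = stratified_report(df, diam).set_index("stratum")
        oracle = df.assign(stratum=[stratum_of(diam[c]) for c in ids]).groupby("stratum")["dsc"].mean()
        for label, val in oracle.items():
            assert abs(rep.loc[label, "dsc"] - val) < 1e-12

    def test_unannotated_case_excluded_with_warning(self):
        df = pd.DataFrame({"case_id": ["a", "b"], "dsc": [0.4, 0.8]})
        with pytest.warns(UserWarning, match="excluded"):
            rep = stratified_report(df, {"a": 2.0})
        assert rep["n_cases"].sum() == 1
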