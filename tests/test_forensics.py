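"""Inflation statistics, duplicate-value tags and threshold rules."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from leakforensics.forensics import (
    best_threshold_rule,
    discordance_scan,
    duplicate_value_clusters,
    inflation_report,
    threshold_rule_eval,
)
from leakforensics.simulate import (
    hepandensovirus_fixture,
    mulikevirus_fixture,
    thiorhodospira_fixture,
)


def _df(rows):
    arr = np.atleast_2d(rows)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"g{j}" for j in range(arr.shape[1])],
    )


class TestInflationReport:
    def test_hand_computed_example(self):
        rep = inflation_report(_df([100, 20, 5]), _df([5, 15, 0]), thresholds=[10])
        e = rep.at(10)
        assert e.n_pairs == 2  # 100 and 20 pass A >= 10
        assert e.n_tenfold == 1  # 100 >= 10*5; 20 < 10*15
        assert e.n_within50 == 1  # 20 within [7.5, 22.5] of 15
        assert e.tenfold_fraction == Fraction(1, 2)

    def test_identity_matrices(self):
        a = _df([[12, 40], [100, 11]])
        rep = inflation_report(a, a, thresholds=[10])
        e = rep.at(10)
        assert e.n_tenfold == 0
        assert e.n_within50 == e.n_pairs == 4

    def test_zero_reference_counts_as_tenfold(self):
        rep = inflation_report(_df([1000]), _df([0]), thresholds=[10])
        assert rep.at(10).n_tenfold == 1
        assert rep.at(10).n_within50 == 0

    def test_antisymmetry_of_roles(self):
        rng = np.random.default_rng(0)
        b = rng.integers(0, 5, size=(20, 10))
        a = b * 100 + 50  # A >> B everywhere
        rep_ab = inflation_report(_df(a), _df(b))
        rep_ba = inflation_report(_df(b), _df(a))
        assert rep_ab.at(10).tenfold_fraction == 1
        ba = rep_ba.at(10)
        assert (ba.n_tenfold or 0) == 0

    def test_id_mismatch_rejected(self):
        a = _df([[1, 2]])
        b = a.rename(columns={"g0": "other"})
        with pytest.raises(ValueError, match="other"):
            inflation_report(a, b)


class TestDuplicateValueClusters:
    def test_constant_column_single_cluster(self):
        assert duplicate_value_clusters(np.full(7, 1.25)) == [(1.25, 7)]

    def test_all_distinct_empty(self):
        assert duplicate_value_clusters(np.arange(10.0)) == []

    def test_rounding_to_nine_significant_digits(self):
        vals = np.array([3.0758742140001, 3.0758742139999, 3.07584214])
        # first two round to 3.07587421, third stays distinct
        clusters = duplicate_value_clusters(vals)
        assert clusters == [(3.07587421, 2)]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            duplicate_value_clusters(np.arange(5.0), group=np.zeros(5, bool))


class TestThresholdRule:
    def test_perfect_separation(self):
        r = threshold_rule_eval([0, 0, 1, 1], [False, False, True, True], 0.5, "ge")
        assert r.sensitivity == 1 and r.specificity == 1 and r.error_rate == 0

    def test_exact_fractions(self):
        r = threshold_rule_eval([1, 2, 3, 4], [False, True, True, False], 2, "ge")
        assert r.sensitivity == Fraction(2, 2)
        assert r.specificity == Fraction(1, 2)
        assert r.error_rate == Fraction(1, 4)

    @given(st.integers(min_value=0, max_value=2000))
    def test_matches_brute_force_confusion(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 5, size=20).astype(float)
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        thr = float(rng.integers(0, 5))
        direction = ["ge", "gt", "le", "lt"][seed % 4]
        r = threshold_rule_eval(values, labels, thr, direction)
        op = {"ge": np.greater_equal, "gt": np.greater,
              "le": np.less_equal, "lt": np.less}[direction]
        tp = sum(1 for v, y in zip(values, labels) if op(v, thr) and y)
        fp = sum(1 for v, y in zip(values, labels) if op(v, thr) and not y)
        fn = sum(1 for v, y in zip(values, labels) if not op(v, thr) and y)
        tn = 20 - tp - fp - fn
        assert (r.tp, r.fp, r.tn, r.fn) == (tp, fp, tn, fn)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        r1 = threshold_rule_eval(values, labels, 0.2, "ge")
        r2 = threshold_rule_eval(np.exp(values), labels, np.exp(0.2), "ge")
        assert r1.sensitivity == r2.sensitivity
        assert r1.specificity == r2.specificity

    def test_one_class_labels_rejected(self):
        with pytest.raises(ValueError):
            threshold_rule_eval([1, 2], [True, True], 1.5)


class TestBestThresholdRule:
    def test_separable_reaches_one(self):
        thr, direction, bacc = best_threshold_rule(
            [0, 0, 1, 1], [False, False, True, True]
        )
        assert bacc == 1.0 and direction == "ge" and thr == 0.5

    def test_low_value_positive_class_found(self):
        thr, direction, bacc = best_threshold_rule(
            [0, 0, 1, 1], [True, True, False, False]
        )
        assert bacc == 1.0 and direction == "le"

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=100)
        labels = np.array([True] * 50 + [False] * 50)
        rng.shuffle(labels)
        _, _, bacc = best_threshold_rule(values, labels)
        assert 0.5 <= bacc < 0.65

    @given(st.integers(min_value=0, max_value=2000))
    def test_balanced_accuracy_at_least_half(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 4, size=12).astype(float)
        labels = rng.random(12) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        _, _, bacc = best_threshold_rule(values, labels)
        assert bacc >= 0.5

    def test_constant_values_degenerate(self):
        thr, direction, bacc = best_threshold_rule(
            [2.0, 2.0, 2.0], [True, False, True]
        )
        assert bacc == 0.5 and thr == 2.0


class TestCaseStudyFixtures:
    def test_hepandensovirus_rule_statistics(self):
        raw, norm, labels = hepandensovirus_fixture()
        r = threshold_rule_eval(
            norm.values["Hepandensovirus"], (labels == "ACC").to_numpy(),
            3.078874655, "ge",
        )
        assert r.sensitivity == Fraction(71, 79)
        assert r.n_errors == 77
        assert r.error_rate == Fraction(77, 17_625)
        assert raw.counts["Hepandensovirus"].sum() == 2
        assert int((raw.counts["Hepandensovirus"] != 0).sum()) == 1

    def test_thiorhodospira_near_disjoint_rule(self):
        raw, norm, labels = thiorhodospira_fixture()
        tumor = (raw.metadata["sample_type"] == "tumor").to_numpy()
        _, _, bacc = best_threshold_rule(norm.values["Thiorhodospira"], tumor)
        assert bacc > 0.95
        assert int((raw.counts["Thiorhodospira"] != 0).sum()) == 7

    def test_mulikevirus_clusters_and_scan(self):
        raw, norm, labels = mulikevirus_fixture()
        normal = (raw.metadata["sample_type"] == "normal").to_numpy()
        clusters = duplicate_value_clusters(norm.values["Mulikevirus"], group=normal)
        assert [c for _, c in clusters[:3]] == [38, 18, 5]
        assert (raw.counts["Mulikevirus"] == 0).all()
        diagnostics = discordance_scan(raw, norm, raw.metadata["sample_type"])
        d = diagnostics[0]
        assert d.flagged
        assert d.best_rule_class == "normal" and d.best_rule_direction == "le"


class TestDiscordanceScan:
    def _zero_feature_inputs(self, leak: bool):
        from leakforensics.containers import CountMatrix, NormalizedMatrix

        rng = np.random.default_rng(7)
        classes = ["A"] * 30 + ["B"] * 30
        idx = [f"s{i}" for i in range(60)]
        counts = pd.DataFrame({"gz": 0, "gn": rng.integers(1, 40, 60)}, index=idx)
        meta = pd.DataFrame(
            {"class_label": classes, "sample_type": "tumor", "library_size": 10_000},
            index=idx,
        )
        raw = CountMatrix(counts, meta)
        if leak:
            gz = np.where(np.array(classes) == "A", 2.0, -1.0)
        else:
            gz = np.full(60, -1.0)
        values = pd.DataFrame(
            {"gz": gz, "gn": rng.normal(size=60)}, index=idx
        )
        norm = NormalizedMatrix(values, {"all_zero_features": ["gz"]})
        return raw, norm, meta["class_label"]

    def test_leaky_zero_feature_flagged(self):
        raw, norm, labels = self._zero_feature_inputs(leak=True)
        diags = {d.feature: d for d in discordance_scan(raw, norm, labels)}
        assert diags["gz"].flagged
        assert not diags["gn"].flagged  # nonzero raw cannot be flagged

    def test_label_blind_zero_feature_not_flagged(self):
        raw, norm, labels = self._zero_feature_inputs(leak=False)
        diags = {d.feature: d for d in discordance_scan(raw, norm, labels)}
        assert not diags["gz"].flagged
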