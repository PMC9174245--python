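import itertools
import math

import numpy as np
import pandas as pd
import pytest

from btcmeth.selection import (
    MarkerPanelClassifier,
    MarkerSet,
    choose_threshold,
    filter_hyper_normal_low,
    overlap_enrichment,
    panel_search,
    replicate_in,
    roc,
    specificity_filter,
)


def _records(rows):
    df = pd.DataFrame(
        rows,
        columns=["cgi_id", "delta_beta", "combined_p", "mean_beta_normal"],
    ).set_index("cgi_id")
    return df


class TestFilters:
    base = _records(
        [
            ("keep", 0.25, 0.01, 0.15),
            ("high_normal", 0.25, 0.01, 0.25),
            ("hypo", -0.30, 0.001, 0.60),
            ("weak", 0.10, 0.01, 0.05),
            ("nonsig", 0.30, 0.20, 0.05),
        ]
    )

    def test_hyper_normal_low_rules(self):
        ms = filter_hyper_normal_low(self.base)
        assert tuple(ms) == ("keep",)
        assert ms.provenance == ("hyper_normal_low",)

    def test_replicate_in_with_untestable(self):
        ms = MarkerSet(("a", "b", "c"))
        other = _records([("a", 0.35, 0.01, 0.1), ("b", 0.10, 0.01, 0.1)])
        out = replicate_in(ms, other)
        assert tuple(out) == ("a",)
        assert out.untestable == ("c",)

    def test_specificity_any_rule_catches_hypo_too(self):
        ms = MarkerSet(("a", "b", "c", "d"))
        others = {
            "COAD": _records([("a", 0.05, 0.5, 0.1), ("b", 0.25, 0.5, 0.1),
                              ("c", -0.25, 0.5, 0.1)]),
            "STAD": _records([("a", 0.10, 0.5, 0.1)]),
        }
        out = specificity_filter(ms, others)
        # b excluded (hyper elsewhere), c excluded (|.| catches hypo),
        # d absent everywhere -> cannot be excluded
        assert tuple(out) == ("a", "d")

    def test_filter_chain_is_monotone_with_provenance(self):
        ms = filter_hyper_normal_low(self.base)
        other = _records([("keep", 0.35, 0.01, 0.1)])
        ms2 = replicate_in(ms, other)
        ms3 = specificity_filter(ms2, {"COAD": other})
        assert set(ms3) <= set(ms2) <= set(ms)
        assert ms3.provenance == (
            "hyper_normal_low", "replicated", "disease_specific"
        )


class TestOverlapEnrichment:
    def test_certain_event(self):
        assert overlap_enrichment(4, 4, 4, 4) == pytest.approx(1.0)
        assert overlap_enrichment(0, 2, 2, 10) == pytest.approx(1.0)

    def test_small_case_enumeration(self):
        # universe {1,2,3,4}, B={1,2}; drawing A of size 2:
        # P(overlap = 2) = 1/C(4,2) = 1/6
        assert overlap_enrichment(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(3, 2, 5, 10)
        with pytest.raises(ValueError):
            overlap_enrichment(1, 2, 5, 4)

    def test_agrees_with_enumeration_small_universes(self):
        def enum_p(k, na, nb, n):
            universe = range(n)
            b = set(range(nb))
            total = hits = 0
            for draw in itertools.combinations(universe, na):
                total += 1
                hits += int(len(b & set(draw)) >= k)
            return hits / total

        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(1, 13))
            na = int(rng.integers(0, n + 1))
            nb = int(rng.integers(0, n + 1))
            k = int(rng.integers(0, min(na, nb) + 1))
            assert overlap_enrichment(k, na, nb, n) == pytest.approx(
                enum_p(k, na, nb, n), abs=1e-12
            )


def _brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        assert roc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_pair_count_oracle_on_example(self):
        # both tumour scores beat the single normal score
        expected = _brute_force_auc([3, 1, 2], [1, 0, 1])
        assert expected == 1.0
        assert roc([3, 1, 2], [1, 0, 1]).auc == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], [1, 1])

    def test_auc_equals_pair_counting_on_random_sets(self, rng):
        """Trapezoidal AUC equals the Mann-Whitney pair statistic."""
        for _ in range(1000):
            n = int(rng.integers(4, 15))
            labels = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            assert roc(scores, labels).auc == pytest.approx(
                _brute_force_auc(scores, labels), abs=1e-12
            )


class TestChooseThreshold:
    def test_perfect_gap_midpoint(self):
        thr = choose_threshold([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert thr == pytest.approx(0.5)

    def test_all_tied_calls_all_negative(self):
        assert choose_threshold([0.3] * 4, [1, 1, 0, 0]) == math.inf

    def test_accuracy_and_youden_can_disagree(self):
        # 1 diseased low scorer among many controls: accuracy prefers
        # missing it; youden trades differently
        scores = [10, 10, 10, 2, 0, 0, 0, 0, 0, 3]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        thr_y = choose_threshold(scores, labels, "youden")
        thr_a = choose_threshold(scores, labels, "accuracy")
        for thr, crit in ((thr_y, "youden"), (thr_a, "accuracy")):
            assert np.isfinite(thr)
        # the borderline control (score 3) is classified positive at
        # the youden cut and negative at the accuracy cut
        assert (3 >= thr_y) != (3 >= thr_a) or thr_y != thr_a

    def test_ties_break_toward_higher_threshold(self):
        # youden is 0.5 both at 1.5 and at 3.5; the more specific
        # (higher) threshold wins
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 1, 0, 1]
        thr = choose_threshold(scores, labels)
        assert thr == pytest.approx(3.5)

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            choose_threshold([1, 2], [0, 1], "f1")


def _panel_fixture():
    """Two complementary markers, each covering half the tumours."""
    tumours = [f"T{i}" for i in range(8)]
    normals = [f"N{i}" for i in range(4)]
    samples = tumours + normals
    cgi_meth = pd.DataFrame(0.05, index=["mA", "mB", "mC"], columns=samples)
    cgi_meth.loc["mA", tumours[:4]] = 0.8
    cgi_meth.loc["mB", tumours[4:]] = 0.8
    cgi_meth.loc["mC", tumours] = 0.3   # weak, covers all
    cgi_meth.loc["mC", normals] = 0.25
    sheet = pd.DataFrame(
        {"group": ["tumour"] * 8 + ["normal"] * 4, "cohort": "train"},
        index=samples,
    )
    return cgi_meth, sheet


class TestMarkerPanelClassifier:
    def test_fit_predict_or_rule(self):
        cgi_meth, sheet = _panel_fixture()
        X = cgi_meth.T
        y = (sheet["group"] == "tumour").astype(int).to_numpy()
        clf = MarkerPanelClassifier(markers=("mA", "mB")).fit(X, y)
        assert set(clf.thresholds_) == {"mA", "mB"}
        assert clf.predict(X).sum() == 8  # all tumours, no normals
        assert clf.decision_function(X).max() == pytest.approx(0.8)

    def test_sklearn_param_interface(self):
        clf = MarkerPanelClassifier(markers=("a",), criterion="accuracy")
        params = clf.get_params()
        assert params["criterion"] == "accuracy"
        clf.set_params(criterion="youden")
        assert clf.criterion == "youden"


class TestPanelSearch:
    def test_complementary_pair_outranks_singletons(self):
        cgi_meth, sheet = _panel_fixture()
        panels = panel_search(
            cgi_meth, sheet, MarkerSet(("mA", "mB")),
            validation={"val": (cgi_meth, sheet)}, max_size=2,
        )
        assert panels[0].markers == ("mA", "mB")
        assert panels[0].validation["val"]["sensitivity"] == 1.0
        assert all(
            p.validation["val"]["sensitivity"] == 0.5 for p in panels[1:]
        )

    def test_perfect_singleton_wins_by_size(self):
        cgi_meth, sheet = _panel_fixture()
        strong = cgi_meth.copy()
        strong.loc["mA", [f"T{i}" for i in range(8)]] = 0.9
        panels = panel_search(
            strong, sheet, MarkerSet(("mA", "mB")),
            validation={"val": (strong, sheet)}, max_size=2,
        )
        assert panels[0].markers == ("mA",)

    def test_ranking_invariant_to_input_order(self):
        cgi_meth, sheet = _panel_fixture()
        val = {"val": (cgi_meth, sheet)}
        p1 = panel_search(cgi_meth, sheet, MarkerSet(("mA", "mB", "mC")),
                          val, max_size=2)
        p2 = panel_search(cgi_meth, sheet, MarkerSet(("mC", "mA", "mB")),
                          val, max_size=2)
        assert [p.markers for p in p1] == [p.markers for p in p2]

    def test_partially_evaluated_ranked_last(self):
        cgi_meth, sheet = _panel_fixture()
        val_missing = cgi_meth.drop(index=["mB"])
        panels = panel_search(
            cgi_meth, sheet, MarkerSet(("mA", "mB")),
            validation={"val": (val_missing, sheet)}, max_size=1,
        )
        assert panels[0].markers == ("mA",) and panels[0].fully_evaluated
        assert not panels[-1].fully_evaluated

    def test_candidate_cap_enforced(self):
        cgi_meth, sheet = _panel_fixture()
        too_many = MarkerSet(tuple(f"m{i}" for i in range(41)))
        with pytest.raises(ValueError, match="cap"):
            panel_search(cgi_meth, sheet, too_many, {}, max_size=1)
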