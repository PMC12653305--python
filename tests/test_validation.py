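import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zndvi.indices import CLASS_NAMES
from zndvi.validation import (
    BinarizationRule,
    ConfusionStats,
    binarize,
    categorize_defoliation,
    cohens_kappa,
    confusion,
    join_series_records,
    kappa_from_counts,
    metrics,
    pooled_report,
    regression_agreement,
)

CATEGORIES = ("None", "Weak", "Medium", "Severe", "Dead")


def brute_kappa(pairs):
    """Marginal-product kappa oracle, independent loop arithmetic."""
    n = len(pairs)
    po = sum(1 for a, b in pairs if a == b) / n
    labels = {l for p in pairs for l in p}
    pe = 0.0
    for l in labels:
        pa = sum(1 for a, _ in pairs if a == l) / n
        pb = sum(1 for _, b in pairs if b == l) / n
        pe += pa * pb
    return (po - pe) / (1 - pe) if pe < 1 else math.nan


class TestCategorize:
    @pytest.mark.parametrize(
        "pct,cat",
        [
            (0, "None"), (5, "None"), (10, "None"),
            (10.5, "Weak"), (25, "Weak"),
            (26, "Medium"), (60, "Medium"),
            (61, "Severe"), (62, "Severe"), (99, "Severe"),
            (99.5, "Dead"), (100, "Dead"),
        ],
    )
    def test_bins(self, pct, cat):
        assert categorize_defoliation(pct) == cat

    @pytest.mark.parametrize("pct", [-1, 101])
    def test_out_of_range(self, pct):
        with pytest.raises(ValueError):
            categorize_defoliation(pct)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 100))
    def test_total_cover(self, pct):
        assert categorize_defoliation(pct) in CATEGORIES


class TestBinarize:
    def test_tp_cell(self):
        assert binarize(0, "Severe") == (True, True)

    def test_tn_cell(self):
        assert binarize(3, "None") == (False, False)

    def test_fn_cell_default_rule(self):
        # moderate satellite class vs Medium field -> (negative, positive)
        assert binarize(2, "Medium") == (False, True)

    def test_full_enumeration_against_mapping_table(self):
        rule = BinarizationRule()
        for code, cat in itertools.product(range(5), CATEGORIES):
            sat, field = binarize(code, cat, rule)
            assert sat == (code in {0, 1})
            assert field == (cat in {"Medium", "Severe", "Dead"})

    def test_custom_rule(self):
        rule = BinarizationRule(
            sat_positive_classes=frozenset({0}),
            field_positive_categories=frozenset({"Dead"}),
        )
        assert binarize(1, "Severe", rule) == (False, False)

    def test_undefined_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            binarize(-1, "None")

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            binarize(0, "Moderate")

    def test_rule_serializes(self):
        d = BinarizationRule().to_dict()
        assert d == {
            "sat_positive_classes": [0, 1],
            "field_positive_categories": ["Dead", "Medium", "Severe"],
        }


class TestConfusion:
    def test_perfect_pairs(self):
        c = confusion([(True, True)] * 5 + [(False, False)] * 5)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 5)

    def test_one_of_each_cell(self):
        c = confusion([(True, True), (True, False), (False, True), (False, False)])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_brute_force_tally_1000_pairs(self):
        rng = np.random.default_rng(6)
        pairs = [(bool(a), bool(b)) for a, b in rng.integers(0, 2, (1000, 2))]
        c = confusion(pairs)
        tp = sum(1 for p, a in pairs if p and a)
        fp = sum(1 for p, a in pairs if p and not a)
        fn = sum(1 for p, a in pairs if not p and a)
        tn = sum(1 for p, a in pairs if not p and not a)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_normalize_total(self):
        c = confusion([(True, True), (False, False)], normalize="total")
        assert (c.tp, c.tn) == (0.5, 0.5)

    def test_normalize_actual(self):
        pairs = [(True, True)] * 3 + [(False, True)] * 1 + [(False, False)] * 4
        c = confusion(pairs, normalize="actual")
        assert c.tp == pytest.approx(0.75)
        assert c.fn == pytest.approx(0.25)
        assert c.tn == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion([])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionStats(tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    def test_2017_row_f1(self):
        # printed components (0.51, 0.49, 0.49, 0.68) -> F1 = 0.51
        m = metrics(ConfusionStats(tp=0.51, fp=0.49, fn=0.49, tn=0.68))
        assert round(m.f1, 2) == 0.51

    def test_2017_row_specificity(self):
        m = metrics(ConfusionStats(tp=0.51, fp=0.49, fn=0.49, tn=0.68))
        assert round(m.specificity, 2) == 0.58

    def test_perfect_classifier_all_ones(self):
        m = metrics(ConfusionStats(tp=1, fp=0, fn=0, tn=1))
        for v in (m.precision, m.sensitivity, m.specificity, m.total_accuracy, m.f1):
            assert v == 1.0

    def test_undefined_marked_nan_not_zero(self):
        m = metrics(ConfusionStats(tp=0, fp=0, fn=3, tn=5))
        assert math.isnan(m.precision)  # no positive predictions
        assert m.sensitivity == 0.0

    def test_f1_harmonic_mean_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 30, 4)
            m = metrics(ConfusionStats(tp=tp, fp=fp, fn=fn, tn=tn))
            if not (math.isnan(m.precision) or math.isnan(m.sensitivity)):
                if m.precision + m.sensitivity > 0:
                    hm = 2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
                    assert m.f1 == pytest.approx(hm, abs=1e-12)

    def test_duplication_invariance(self):
        pairs = [(True, True), (True, False), (False, True), (False, False),
                 (True, True)]
        m1 = metrics(confusion(pairs))
        m2 = metrics(confusion(pairs * 3))
        for attr in ("precision", "sensitivity", "specificity", "total_accuracy", "f1"):
            assert getattr(m1, attr) == pytest.approx(getattr(m2, attr))


class TestKappa:
    def test_identical_labelings_kappa_one(self):
        pairs = [(l, l) for l in ("a", "b", "c", "a", "b")]
        assert cohens_kappa(pairs) == 1.0

    def test_constant_vs_balanced_kappa_zero(self):
        # one rater constant, other balanced: p_o = p_e = 0.5 -> k = 0
        pairs = [("P", "P"), ("P", "N")] * 10
        assert cohens_kappa(pairs) == pytest.approx(0.0, abs=1e-12)

    def test_counts_45_15_25_15_matches_marginal_oracle(self):
        tp, fp, fn, tn = 45, 15, 25, 15
        pairs = (
            [(True, True)] * tp + [(True, False)] * fp
            + [(False, True)] * fn + [(False, False)] * tn
        )
        k = kappa_from_counts(tp, fp, fn, tn)
        assert k == pytest.approx(brute_kappa(pairs), abs=1e-12)
        assert k == pytest.approx(cohens_kappa(pairs), abs=1e-12)
        # independent arithmetic: po=0.6, pe=0.6*0.7+0.4*0.3=0.54
        assert k == pytest.approx((0.6 - 0.54) / 0.46, abs=1e-12)

    def test_total_agreement_on_one_label_undefined(self):
        assert math.isnan(cohens_kappa([("x", "x"), ("x", "x")]))

    def test_multiclass_against_oracle(self):
        rng = np.random.default_rng(9)
        pairs = [
            (CLASS_NAMES[a], CATEGORIES[b])
            for a, b in rng.integers(0, 5, (500, 2))
        ]
        assert cohens_kappa(pairs) == pytest.approx(brute_kappa(pairs), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_kappa_in_range_or_nan(self, pairs):
        k = cohens_kappa(pairs)
        assert math.isnan(k) or -1.0 <= k <= 1.0 + 1e-12

    def test_kappa_one_iff_po_one(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pairs = [
                (bool(a), bool(b)) for a, b in rng.integers(0, 2, (50, 2))
            ]
            k = cohens_kappa(pairs)
            po = sum(a == b for a, b in pairs) / len(pairs)
            if not math.isnan(k):
                assert (k == 1.0) == (po == 1.0)


class TestRegressionAgreement:
    def test_perfect_linear(self):
        z = [-2.0, -1.0, 0.0, 1.0]
        defol = [45.0, 35.0, 25.0, 15.0]
        r2, rmse = regression_agreement(z, defol)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_rmse_in_percent_units_scales(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=30)
        defol = 20 - 10 * z + rng.normal(size=30)
        _, rmse1 = regression_agreement(z, defol)
        _, rmse10 = regression_agreement(z, defol * 2)
        assert rmse10 == pytest.approx(2 * rmse1, rel=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3 complete"):
            regression_agreement([1.0, 2.0], [3.0, 4.0])

    def test_nan_pairs_dropped(self):
        z = [1.0, 2.0, 3.0, float("nan")]
        defol = [2.0, 4.0, 6.0, 8.0]
        r2, _ = regression_agreement(z, defol, sign=1.0)
        assert r2 == pytest.approx(1.0)


def _joined_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["plot_id", "level", "year", "z_mean", "sat_class",
                 "defoliation_pct", "defoliation_category"],
    )


class TestPooledReport:
    def test_single_stratum_equals_pooled(self):
        rows = [
            ("P1", "I", 2020, -2.5, 0, 70.0, "Severe"),
            ("P2", "I", 2020, 0.5, 3, 5.0, "None"),
            ("P3", "I", 2020, -1.5, 1, 40.0, "Medium"),
        ]
        reports = pooled_report(_joined_frame(rows), strata="year")
        assert len(reports) == 2  # the year + pooled
        year_rep, pooled = reports
        assert year_rep.stats == pooled.stats
        assert year_rep.n == pooled.n == 3

    def test_identical_strata_equal_pooled_rates(self):
        rows = [
            ("P1", "I", 2020, -2.5, 0, 70.0, "Severe"),
            ("P2", "I", 2020, 0.5, 3, 5.0, "None"),
            ("P1", "I", 2021, -2.5, 0, 70.0, "Severe"),
            ("P2", "I", 2021, 0.5, 3, 5.0, "None"),
        ]
        reports = {r.stratum: r for r in pooled_report(_joined_frame(rows), "year")}
        m2020 = metrics(reports["2020"].stats)
        mpool = metrics(reports["pooled"].stats)
        assert m2020.total_accuracy == mpool.total_accuracy
        assert m2020.f1 == mpool.f1

    def test_missing_bookkeeping(self):
        rows = [
            ("P1", "I", 2020, -2.5, 0, 70.0, "Severe"),
            ("P2", "I", 2020, float("nan"), -1, 5.0, "None"),  # unclassified
        ]
        reports = {r.stratum: r for r in pooled_report(_joined_frame(rows), "year")}
        assert reports["2020"].n == 1
        assert reports["2020"].n_missing == 1

    def test_empty_stratum_skipped(self):
        rows = [
            ("P1", "I", 2020, -2.5, 0, 70.0, "Severe"),
            ("P2", "I", 2021, float("nan"), -1, 5.0, "None"),
        ]
        strata = [r.stratum for r in pooled_report(_joined_frame(rows), "year")]
        assert "2021" not in strata

    def test_unknown_strata(self):
        with pytest.raises(ValueError, match="strata"):
            pooled_report(_joined_frame([]), strata="species")

    def test_missing_count_matches_injected_missingness(self, disturbed_config):
        import dataclasses

        from zndvi.indices import ndvi, z_ndvi
        from zndvi.plots import extract_plot_z
        from zndvi.preprocess import mask_pixels, median_composite
        from zndvi.synthetic import simulate_plots, simulate_scenes

        cfg = dataclasses.replace(disturbed_config, n_plots_level1=10, n_plots_level2=2)
        scenes, truth = simulate_scenes(cfg)
        records = simulate_plots(cfg, truth)
        nd = {}
        for y, ss in scenes.items():
            comp = median_composite([mask_pixels(s) for s in ss], y)
            nd[y] = np.where(comp.valid_mask, ndvi(comp.red, comp.nir), np.nan)
        # knock out one year entirely for one plot's window
        anoms = z_ndvi(nd).classify_all()
        victim = records[0]
        r0, r1 = max(0, victim.row - 1), victim.row + 2
        c0, c1 = max(0, victim.col - 1), victim.col + 2
        anoms.z[2019][r0:r1, c0:c1] = np.nan
        anoms.classes[2019][r0:r1, c0:c1] = -1
        series = extract_plot_z(anoms, records, window=1)
        joined = join_series_records(series, records)
        reports = {r.stratum: r for r in pooled_report(joined, "year")}
        assert reports["2019"].n_missing == 1
        assert reports["pooled"].n_missing == 1
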