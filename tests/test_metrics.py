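"""Confusion arithmetic, curves, margin reports, and subject splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, seed as hyp_seed, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from octmargin.metrics import (
    ConfusionCounts,
    confusion_metrics,
    counts_from_rates,
    margin_report,
    mcc_from_counts,
    roc_pr,
    split_subjects,
    threshold_table,
)
from octmargin.postproc import Cluster, Detection, PatchPrediction, TierConfig


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert m.mcc == 1.0
        assert m.f1_macro == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_all_negative_predictor(self):
        # the degenerate threshold-1.0 operating point of the reference table
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=97, fn=3), threshold=1.0)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.mcc == 0.0
        assert m.plr is None  # reported as absent, not zero
        assert m.nlr == 1.0

    def test_undefined_ratios_are_none(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=5))
        assert m.ppv is None and m.specificity is None

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @hyp_seed(3)
    @settings(max_examples=200, deadline=None)
    def test_mcc_matches_sklearn(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        assert mcc_from_counts(c) == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-9
        )
        assert -1.0 <= mcc_from_counts(c) <= 1.0

    def test_mcc_symmetric_under_class_swap(self):
        c = ConfusionCounts(tp=30, fp=7, tn=200, fn=11)
        swapped = ConfusionCounts(tp=200, fp=11, tn=30, fn=7)
        assert mcc_from_counts(c) == pytest.approx(mcc_from_counts(swapped))


class TestPrintedTableReconstruction:
    """The reference operating table's rows must be reproducible from their
    own printed sensitivity/specificity and the dataset's totals."""

    POSITIVES, TOTAL = 3736, 255_682

    def test_sensitive_operating_point(self):
        c = counts_from_rates(0.928, 0.98, self.POSITIVES, self.TOTAL)
        m = confusion_metrics(c, threshold=0.75)
        assert m.mcc == pytest.approx(0.609, abs=0.01)
        assert m.ppv == pytest.approx(0.41, abs=0.01)
        assert m.plr == pytest.approx(46.40, abs=0.05)
        assert m.nlr == pytest.approx(0.07, abs=0.005)
        assert m.f1_macro == pytest.approx(0.779, abs=0.002)

    @pytest.mark.parametrize(
        "sens,spec,expected_f1",
        [(0.96, 0.969, 0.73), (0.928, 0.98, 0.779), (0.702, 0.997, 0.868)],
    )
    def test_macro_f1_reconstruction(self, sens, spec, expected_f1):
        c = counts_from_rates(sens, spec, self.POSITIVES, self.TOTAL)
        m = confusion_metrics(c)
        assert m.f1_macro == pytest.approx(expected_f1, abs=0.002)

    def test_selective_likelihood_ratio(self):
        c = counts_from_rates(0.702, 0.997, self.POSITIVES, self.TOTAL)
        m = confusion_metrics(c, threshold=0.925)
        assert m.plr == pytest.approx(234.00, abs=0.5)


class TestRocPr:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        auroc, auprc, prev = roc_pr(labels, scores)
        assert auroc == 1.0 and auprc == 1.0
        assert prev == pytest.approx(0.4)

    def test_inverted_scores(self):
        labels = np.array([0, 0, 1, 1])
        auroc, _, _ = roc_pr(labels, np.array([0.9, 0.8, 0.2, 0.1]))
        assert auroc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr(np.zeros(10), np.random.default_rng(0).random(10))

    def test_random_scorer_auprc_near_prevalence(self, rng):
        n, prevalence = 50_000, 0.05
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)  # independent of labels
        _, auprc, base = roc_pr(labels, scores)
        assert auprc == pytest.approx(base, abs=0.02)
        assert base == pytest.approx(prevalence, abs=0.01)


def test_threshold_table_columns_and_degenerate_row(rng):
    labels = (rng.random(500) < 0.2).astype(int)
    scores = np.clip(rng.normal(0.3 + 0.4 * labels, 0.2), 0, 1)
    table = threshold_table(labels, scores)
    assert list(table.columns) == [
        "threshold", "sensitivity", "specificity", "f1_score",
        "mcc", "ppv", "npv", "plr", "nlr",
    ]
    last = table.iloc[-1]  # threshold 1.0
    if last["sensitivity"] == 0.0:
        assert last["mcc"] == 0.0


class TestMarginReport:
    """A hand-built two-margin scenario with known truth."""

    def _scenario(self):
        cfg = TierConfig()

        def pred(m, b, g, prob, label):
            return PatchPrediction("S0", m, b, g, g * 94, prob, label)

        patches = [
            # margin A: positive, lesion on bscans 0-1 col 2
            pred("A", 0, 2, 0.95, "positive"),
            pred("A", 1, 2, 0.90, "positive"),
            pred("A", 0, 0, 0.10, "negative"),
            pred("A", 1, 5, 0.80, "negative"),   # isolated false detection
            pred("A", 2, 2, 0.20, "positive"),   # missed positive
            # margin B: negative throughout
            pred("B", 0, 0, 0.10, "negative"),
            pred("B", 1, 1, 0.20, "negative"),
        ]
        from octmargin.postproc import cluster_detections, threshold_detections

        dets = threshold_detections(patches, cfg)
        clusters, discarded = cluster_detections([d for d in dets if d.margin_id == "A"], cfg)
        return patches, dets, clusters, discarded, cfg

    def test_fields(self):
        patches, dets, clusters, discarded, cfg = self._scenario()
        rep = margin_report(["A", "B"], patches, dets, clusters, cfg, tier=1)
        assert rep.n_margins == 2 and rep.n_positive_margins == 1
        assert rep.margins_with_clusters == 1
        assert rep.tp_patches == 2 and rep.fn_patches == 1
        assert rep.fp_patches == 1 and rep.tn_patches == 3
        assert rep.discarded_singles_tn == 1 and rep.discarded_singles_tp == 0
        assert rep.clusters_total == 1 and rep.clusters_with_tp == 1
        assert rep.tp_key_thumbnails == 1
        assert rep.tp_pct == pytest.approx(100 * 2 / 3)
        assert rep.identification_pct == 100.0
        assert rep.avg_detections_positive_margin == 3.0
        assert rep.avg_detections_negative_margin == 0.0

    def test_conservation(self):
        patches, dets, clusters, discarded, cfg = self._scenario()
        rep = margin_report(["A", "B"], patches, dets, clusters, cfg, tier=1)
        clustered = sum(len(c.members) for c in clusters)
        assert clustered + rep.discarded_singles_tp + rep.discarded_singles_tn == len(dets)
        assert rep.tp_patches + rep.fn_patches == sum(
            1 for p in patches if p.label == "positive"
        )

    def test_percentages_recompute_from_counts(self):
        patches, dets, clusters, _, cfg = self._scenario()
        rep = margin_report(["A", "B"], patches, dets, clusters, cfg, tier=1)
        assert rep.tp_pct == pytest.approx(
            100 * rep.tp_patches / (rep.tp_patches + rep.fn_patches)
        )
        assert rep.fp_pct == pytest.approx(
            100 * rep.fp_patches / (rep.fp_patches + rep.tn_patches)
        )

    def test_margin_without_patches_rejected(self):
        patches, dets, clusters, _, cfg = self._scenario()
        with pytest.raises(ValueError, match="without patches"):
            margin_report(["A", "B", "C"], patches, dets, clusters, cfg)


class TestSplitSubjects:
    def _table(self, n_subjects=10, margins_per_subject=2, n_positive_subjects=4, seed=0):
        rows = []
        for s in range(n_subjects):
            for m in range(margins_per_subject):
                rows.append(
                    {
                        "subject_id": f"S{s:02d}",
                        "margin_id": f"S{s:02d}_M{m}",
                        "is_positive": s < n_positive_subjects and m == 0,
                    }
                )
        return pd.DataFrame(rows)

    def test_test_subjects_disjoint(self):
        table = self._table()
        split = split_subjects(table, {"train": 0.5, "val": 0.2, "test": 0.3}, seed=1)
        margin_to_subject = dict(zip(table.margin_id, table.subject_id))
        test_subjects = {margin_to_subject[m] for m in split["test"]}
        trainval_subjects = {
            margin_to_subject[m] for m in split["train"] + split["val"]
        }
        assert len(test_subjects) == 3  # round(0.3 * 10)
        assert not (test_subjects & trainval_subjects)
        # every margin lands in exactly one split
        all_margins = sorted(split["train"] + split["val"] + split["test"])
        assert all_margins == sorted(table.margin_id)

    def test_deterministic_under_seed(self):
        table = self._table()
        assert split_subjects(table, seed=7) == split_subjects(table, seed=7)
        assert split_subjects(table, seed=7) != split_subjects(table, seed=8)

    @pytest.mark.parametrize("seed", range(8))
    def test_positives_in_every_split_when_feasible(self, seed):
        table = self._table(n_subjects=8, n_positive_subjects=4, seed=seed)
        split = split_subjects(table, seed=seed)
        positive = set(table.loc[table.is_positive, "margin_id"])
        for name in ("train", "val", "test"):
            assert positive & set(split[name]), f"no positive margin in {name}"

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            split_subjects(self._table(n_subjects=2))

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            split_subjects(self._table(n_positive_subjects=0))


def test_curve_table_has_roc_and_pr_columns(rng):
    labels = (rng.random(300) < 0.3).astype(int)
    scores = np.clip(rng.normal(0.3 + 0.3 * labels, 0.2), 0, 1)
    from octmargin.metrics import curve_table

    table = curve_table(labels, scores)
    assert list(table.columns) == ["threshold", "fpr", "tpr", "precision", "recall"]
    assert table["fpr"].between(0, 1).all() and table["tpr"].between(0, 1).all()
    # ROC endpoints are present
    assert table["tpr"].min() == 0.0 and table["tpr"].max() == 1.0
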