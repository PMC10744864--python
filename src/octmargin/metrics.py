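"""Imbalance-aware evaluation: confusion arithmetic, curves, margin reports.

Patch-level classification of margin scans is extremely imbalanced (positive
patch fractions of 0.03–1.5%), so the summary statistics here emphasize
measures robust to imbalance: Matthews correlation coefficient

    MCC = (TN·TP − FN·FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

macro-averaged F1 (the mean of the positive- and negative-class F1 scores),
positive/negative likelihood ratios (sens/(1−spec), (1−sens)/spec), and the
precision–recall curve whose random-classifier baseline equals the positive
prevalence. Margin-level reports aggregate detections and clusters into the
operating-point tables a clinical reader would see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from octmargin.patchgen import POSITIVE
from octmargin.postproc import Cluster, Detection, PatchPrediction, TierConfig

__all__ = [
    "ConfusionCounts",
    "ThresholdMetrics",
    "confusion_metrics",
    "counts_from_rates",
    "roc_pr",
    "threshold_table",
    "MarginReport",
    "margin_report",
    "split_subjects",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("empty confusion matrix")


@dataclass(frozen=True)
class ThresholdMetrics:
    """All derived statistics at one operating point.

    Ratios that are undefined for the given counts (division by zero) are
    ``None`` — reported as absent, never silently zero. The printed F1 of the
    reference operating tables is macro-averaged over both classes;
    ``f1_positive`` is also exported.
    """

    threshold: float
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1_positive: float
    f1_negative: float
    f1_macro: float
    mcc: float
    plr: float | None
    nlr: float | None


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def _f1(precision: float | None, recall: float | None) -> float:
    if precision is None or recall is None or precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal total is zero."""
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tn * tp - fn * fp) / math.sqrt(denom)


def confusion_metrics(counts: ConfusionCounts, threshold: float = 0.5) -> ThresholdMetrics:
    """Every operating-point statistic derived from one confusion matrix."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    f1_pos = _f1(ppv, sens)
    f1_neg = _f1(npv, spec)
    plr = None
    if sens is not None and spec is not None and spec < 1.0:
        plr = sens / (1.0 - spec)
    nlr = None
    if sens is not None and spec is not None and spec > 0.0:
        nlr = (1.0 - sens) / spec
    return ThresholdMetrics(
        threshold=threshold,
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f1_positive=f1_pos,
        f1_negative=f1_neg,
        f1_macro=0.5 * (f1_pos + f1_neg),
        mcc=mcc_from_counts(counts),
        plr=plr,
        nlr=nlr,
    )


def counts_from_rates(
    sensitivity: float, specificity: float, positives: int, total: int
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed (rounded) rates."""
    negatives = total - positives
    tp = int(round(sensitivity * positives))
    tn = int(round(specificity * negatives))
    return ConfusionCounts(tp=tp, fp=negatives - tn, tn=tn, fn=positives - tp)


def roc_pr(labels: np.ndarray, probabilities: np.ndarray) -> tuple[float, float, float]:
    """(AUROC, AUPRC, prevalence baseline) for binary labels and scores.

    AUPRC uses precision–recall step integration (average precision); the
    baseline of a label-independent scorer is the positive prevalence.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute curves")
    auroc = float(roc_auc_score(labels, probabilities))
    auprc = float(average_precision_score(labels, probabilities))
    prevalence = float(np.mean(labels))
    return auroc, auprc, prevalence


def threshold_table(
    labels: np.ndarray,
    probabilities: np.ndarray,
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.75, 0.8, 0.9, 0.925, 1.0),
) -> pd.DataFrame:
    """Operating-point table (one row per threshold; probability ≥ threshold
    counts as a positive call). Undefined ratios appear as NaN."""
    labels = np.asarray(labels).astype(bool)
    probabilities = np.asarray(probabilities)
    rows = []
    for t in thresholds:
        pred = probabilities >= t
        c = ConfusionCounts(
            tp=int(np.sum(pred & labels)),
            fp=int(np.sum(pred & ~labels)),
            tn=int(np.sum(~pred & ~labels)),
            fn=int(np.sum(~pred & labels)),
        )
        m = confusion_metrics(c, threshold=t)
        rows.append(
            {
                "threshold": t,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "f1_score": m.f1_macro,
                "mcc": m.mcc,
                "ppv": m.ppv,
                "npv": m.npv,
                "plr": m.plr,
                "nlr": m.nlr,
            }
        )
    return pd.DataFrame(rows)


def curve_table(labels: np.ndarray, probabilities: np.ndarray) -> pd.DataFrame:
    """ROC and precision–recall curve points, one row per score threshold.

    Columns: threshold, fpr, tpr, precision, recall (tpr == recall).
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute curves")
    fpr, tpr, roc_thr = roc_curve(labels, probabilities)
    roc = pd.DataFrame({"threshold": roc_thr, "fpr": fpr, "tpr": tpr})
    precision, recall, pr_thr = precision_recall_curve(labels, probabilities)
    pr = pd.DataFrame(
        {"threshold": np.append(pr_thr, np.inf),
         "precision": precision, "recall": recall}
    )
    merged = pd.merge_asof(
        roc.sort_values("threshold"),
        pr.sort_values("threshold"),
        on="threshold",
        direction="nearest",
    )
    return merged.sort_values("threshold", ignore_index=True)


# ---------------------------------------------------------------------------
# Margin-level report


@dataclass
class MarginReport:
    """Operating-point statistics aggregated to the margin level."""

    tier: int
    threshold: float
    n_margins: int
    n_positive_margins: int
    margins_with_clusters: int          # among positive margins
    margins_with_tp_key_thumbnails: int  # among positive margins
    tp_patches: int
    fn_patches: int
    tn_patches: int
    fp_patches: int
    discarded_singles_tp: int
    discarded_singles_tn: int
    clusters_total: int
    clusters_with_tp: int
    tp_key_thumbnails: int
    avg_detections_positive_margin: float
    avg_detections_negative_margin: float
    avg_clusters_positive_margin: float
    avg_clusters_negative_margin: float

    @property
    def tp_pct(self) -> float:
        return 100.0 * self.tp_patches / max(self.tp_patches + self.fn_patches, 1)

    @property
    def fn_pct(self) -> float:
        return 100.0 * self.fn_patches / max(self.tp_patches + self.fn_patches, 1)

    @property
    def tn_pct(self) -> float:
        return 100.0 * self.tn_patches / max(self.tn_patches + self.fp_patches, 1)

    @property
    def fp_pct(self) -> float:
        return 100.0 * self.fp_patches / max(self.tn_patches + self.fp_patches, 1)

    @property
    def identification_pct(self) -> float:
        """Share of positive margins containing at least one cluster."""
        return 100.0 * self.margins_with_clusters / max(self.n_positive_margins, 1)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k in ("tp_pct", "fn_pct", "tn_pct", "fp_pct", "identification_pct"):
            d[k] = getattr(self, k)
        return d


def margin_report(
    margins: Sequence[str],
    labeled_patches: Sequence[PatchPrediction],
    detections: Sequence[Detection],
    clusters: Sequence[Cluster],
    tier_cfg: TierConfig = TierConfig(),
    tier: int = 1,
) -> MarginReport:
    """Aggregate one tier's detections and clusters into a margin report.

    ``labeled_patches`` must carry ground-truth labels; a detection is a true
    positive iff its patch is labeled positive, a margin is "identified" iff
    it contains at least one cluster, and a key thumbnail is true iff its
    detection's patch is positive. Detections absent from every cluster are
    the discarded singles, split by their ground-truth label.
    """
    margins = list(margins)
    if not margins:
        raise ValueError("no margins to report on")
    patches_by_margin: dict[str, list[PatchPrediction]] = {m: [] for m in margins}
    for p in labeled_patches:
        if p.label is None:
            raise ValueError("labeled_patches must carry ground-truth labels")
        if p.margin_id not in patches_by_margin:
            raise ValueError(f"patch references unknown margin {p.margin_id}")
        patches_by_margin[p.margin_id].append(p)
    empty = [m for m, ps in patches_by_margin.items() if not ps]
    if empty:
        raise ValueError(f"margin(s) without patches: {', '.join(empty)}")

    positive_margins = {
        m for m, ps in patches_by_margin.items() if any(p.label == POSITIVE for p in ps)
    }

    threshold = tier_cfg.threshold_t1 if tier == 1 else tier_cfg.threshold_t2
    det_keys = {(d.margin_id, d.bscan_index, d.grid_col_index) for d in detections}
    tp = sum(1 for d in detections if d.label == POSITIVE)
    fp = len(detections) - tp
    n_pos_patches = sum(1 for p in labeled_patches if p.label == POSITIVE)
    fn = n_pos_patches - tp
    tn = len(labeled_patches) - n_pos_patches - fp

    clustered_keys = {
        (d.margin_id, d.bscan_index, d.grid_col_index) for c in clusters for d in c.members
    }
    singles = [d for d in detections if (d.margin_id, d.bscan_index, d.grid_col_index) not in clustered_keys]
    singles_tp = sum(1 for d in singles if d.label == POSITIVE)

    margins_with_clusters = {c.margin_id for c in clusters}
    clusters_with_tp = sum(1 for c in clusters if any(m.label == POSITIVE for m in c.members))
    tp_keys = sum(1 for c in clusters if c.key.label == POSITIVE)
    margins_with_tp_key = {c.margin_id for c in clusters if c.key.label == POSITIVE}

    n_pos = len(positive_margins)
    n_neg = len(margins) - n_pos
    det_pos = sum(1 for d in detections if d.margin_id in positive_margins)
    clu_pos = sum(1 for c in clusters if c.margin_id in positive_margins)

    if det_keys != {(d.margin_id, d.bscan_index, d.grid_col_index) for d in detections}:
        raise ValueError("duplicate detections")

    return MarginReport(
        tier=tier,
        threshold=threshold,
        n_margins=len(margins),
        n_positive_margins=n_pos,
        margins_with_clusters=len(margins_with_clusters & positive_margins),
        margins_with_tp_key_thumbnails=len(margins_with_tp_key & positive_margins),
        tp_patches=tp,
        fn_patches=fn,
        tn_patches=tn,
        fp_patches=fp,
        discarded_singles_tp=singles_tp,
        discarded_singles_tn=len(singles) - singles_tp,
        clusters_total=len(clusters),
        clusters_with_tp=clusters_with_tp,
        tp_key_thumbnails=tp_keys,
        avg_detections_positive_margin=det_pos / n_pos if n_pos else 0.0,
        avg_detections_negative_margin=(len(detections) - det_pos) / n_neg if n_neg else 0.0,
        avg_clusters_positive_margin=clu_pos / n_pos if n_pos else 0.0,
        avg_clusters_negative_margin=(len(clusters) - clu_pos) / n_neg if n_neg else 0.0,
    )


# ---------------------------------------------------------------------------
# Subject-disjoint splitting


def split_subjects(
    subject_table: pd.DataFrame,
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Split margins into train/val/test with a subject-disjoint test set.

    ``subject_table`` needs columns ``subject_id``, ``margin_id``,
    ``is_positive``. Margins of the same subject may appear in both train and
    val, but every test subject is excluded from train and val entirely.
    Positive margins are placed in every split whenever at least three
    positive subjects exist; otherwise positives go preferentially to train.
    Deterministic under ``seed``.
    """
    fractions = dict(fractions or {"train": 0.6, "val": 0.2, "test": 0.2})
    if set(fractions) != {"train", "val", "test"} or not math.isclose(sum(fractions.values()), 1.0):
        raise ValueError("fractions must cover train/val/test and sum to 1")
    required = {"subject_id", "margin_id", "is_positive"}
    if not required.issubset(subject_table.columns):
        raise ValueError(f"subject_table must have columns {sorted(required)}")
    if subject_table["margin_id"].duplicated().any():
        raise ValueError("margin_id values must be unique")

    subjects = subject_table.groupby("subject_id")["is_positive"].any()
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subjects to split, got {len(subjects)}")
    if not subjects.any():
        raise ValueError("no positive margins present; stratified split infeasible")

    rng = np.random.default_rng(seed)
    pos_subjects = sorted(subjects[subjects].index)
    neg_subjects = sorted(subjects[~subjects].index)
    rng.shuffle(pos_subjects)
    rng.shuffle(neg_subjects)

    n_subjects = len(subjects)
    n_test = max(1, round(fractions["test"] * n_subjects))
    if n_test >= n_subjects:
        raise ValueError("test fraction leaves no subjects for training")

    # Put positive subjects in test only when enough remain for train and val.
    n_test_pos = 0
    if len(pos_subjects) >= 3:
        n_test_pos = min(max(1, round(fractions["test"] * len(pos_subjects))),
                         len(pos_subjects) - 2)
    test_subjects = set(pos_subjects[:n_test_pos])
    for s in neg_subjects:
        if len(test_subjects) >= n_test:
            break
        test_subjects.add(s)
    for s in pos_subjects[n_test_pos:]:
        if len(test_subjects) >= n_test:
            break
        test_subjects.add(s)

    rest = subject_table[~subject_table["subject_id"].isin(test_subjects)]
    if rest.empty:
        raise ValueError("no margins left for train/val after the test split")
    margins = list(rest.itertuples(index=False))
    rng.shuffle(margins)
    denom = fractions["train"] + fractions["val"]
    n_val = round(fractions["val"] / denom * len(margins))
    n_val = min(max(n_val, 1), len(margins) - 1)
    val = margins[:n_val]
    tr = margins[n_val:]

    # Guarantee a positive margin in both train and val when feasible.
    def _swap_for_positive(need: list, donor: list) -> None:
        if any(m.is_positive for m in need) or not any(m.is_positive for m in donor):
            return
        if sum(m.is_positive for m in donor) < 2 and not any(m.is_positive for m in need):
            pass  # donor keeps at least one positive only if it has >= 2
        gi = next(i for i, m in enumerate(donor) if m.is_positive)
        bi = next((i for i, m in enumerate(need) if not m.is_positive), None)
        if bi is None:
            return
        donor[gi], need[bi] = need[bi], donor[gi]

    if sum(m.is_positive for m in margins) >= 2:
        _swap_for_positive(val, tr)
        _swap_for_positive(tr, val)

    return {
        "train": sorted(m.margin_id for m in tr),
        "val": sorted(m.margin_id for m in val),
        "test": sorted(subject_table.loc[
            subject_table["subject_id"].isin(test_subjects), "margin_id"
        ]),
    }
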