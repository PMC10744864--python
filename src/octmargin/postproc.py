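"""Two-tier thresholding, detection clustering, and key-thumbnail selection.

Per-patch probabilities become *detections* at two nested operating points
(a sensitive tier-1 threshold, default 0.75, and a selective tier-2
threshold, default 0.925). Detections live on the integer (B-scan index,
grid column index) lattice; density-based clustering with Chebyshev
adjacency joins detections in neighboring B-scans at the same or adjacent
lateral positions, and isolated detections are discarded as noise — the
morphology of DCIS/IDC makes genuine lesions span at least two adjacent
B-scans. Each cluster is summarized by a single "key thumbnail" chosen by
the moving-average-maximum (MA_MAX) rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.cluster import DBSCAN

from octmargin.phantom import MarginVolume

__all__ = [
    "TierConfig",
    "PatchPrediction",
    "Detection",
    "Cluster",
    "threshold_detections",
    "cluster_detections",
    "select_key_thumbnail",
    "rank_clusters",
    "render_thumbnail",
    "detections_to_frame",
]


@dataclass(frozen=True)
class TierConfig:
    threshold_t1: float = 0.75
    threshold_t2: float = 0.925
    min_cluster_size: int = 2
    ma_window: int = 3
    adjacency_eps: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.threshold_t1 < self.threshold_t2 <= 1:
            raise ValueError("thresholds must satisfy 0 < t1 < t2 <= 1")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.adjacency_eps < 1:
            raise ValueError("adjacency_eps must be >= 1")


@dataclass(frozen=True)
class PatchPrediction:
    """One patch's location and model probability (optionally its truth label)."""

    subject_id: str
    margin_id: str
    bscan_index: int
    grid_col_index: int
    x_start: int
    probability: float
    label: str | None = None


@dataclass(frozen=True)
class Detection:
    """A patch whose probability reaches at least the tier-1 threshold."""

    subject_id: str
    margin_id: str
    bscan_index: int
    grid_col_index: int
    x_start: int
    probability: float
    tier: int  # 2 iff probability >= t2 (tier-2 detections also count in tier 1)
    label: str | None = None


@dataclass
class Cluster:
    """>= min_cluster_size mutually adjacent detections plus its key member."""

    members: list[Detection]
    key_index: int = 0

    @property
    def key(self) -> Detection:
        return self.members[self.key_index]

    @property
    def confidence(self) -> float:
        return self.key.probability

    @property
    def margin_id(self) -> str:
        return self.members[0].margin_id

    def __len__(self) -> int:
        return len(self.members)


def threshold_detections(
    predictions: Sequence[PatchPrediction], tier_cfg: TierConfig = TierConfig()
) -> list[Detection]:
    """Keep predictions at or above the sensitive tier-1 threshold.

    A detection is tier 2 when it also reaches the selective threshold;
    tier-2 detections are a subset of tier-1 detections.
    """
    out = []
    for p in predictions:
        if not 0.0 <= p.probability <= 1.0:
            raise ValueError(f"probability {p.probability} outside [0, 1]")
        if p.probability >= tier_cfg.threshold_t1:
            tier = 2 if p.probability >= tier_cfg.threshold_t2 else 1
            out.append(
                Detection(
                    p.subject_id, p.margin_id, p.bscan_index, p.grid_col_index,
                    p.x_start, p.probability, tier, p.label,
                )
            )
    return out


def cluster_detections(
    detections: Sequence[Detection], tier_cfg: TierConfig = TierConfig()
) -> tuple[list[Cluster], list[Detection]]:
    """Density-cluster one margin's detections on the B-scan × grid lattice.

    Neighbors are lattice points within Chebyshev distance ``adjacency_eps``
    (8-connectivity at the default eps of 1); groups smaller than
    ``min_cluster_size`` are discarded as noise. Returns ``(clusters,
    discarded_singletons)``; every input detection appears in exactly one of
    the two. Each cluster's members are ordered along the scan axis
    (lexicographically by B-scan then grid column) and its key thumbnail is
    selected by :func:`select_key_thumbnail`.
    """
    if len(detections) == 0:
        return [], []
    margins = {d.margin_id for d in detections}
    if len(margins) > 1:
        raise ValueError("cluster_detections operates on a single margin at a time")

    coords = np.array([[d.bscan_index, d.grid_col_index] for d in detections], dtype=float)
    labels = DBSCAN(
        eps=tier_cfg.adjacency_eps, min_samples=2, metric="chebyshev"
    ).fit_predict(coords)

    clusters: list[Cluster] = []
    discarded: list[Detection] = []
    for lab in sorted(set(labels)):
        members = [d for d, l in zip(detections, labels) if l == lab]
        if lab == -1 or len(members) < tier_cfg.min_cluster_size:
            discarded.extend(members)
            continue
        members.sort(key=lambda d: (d.bscan_index, d.grid_col_index))
        cluster = Cluster(members=members)
        cluster.key_index = select_key_thumbnail(cluster, tier_cfg)
        clusters.append(cluster)
    return clusters, discarded


def select_key_thumbnail(cluster: Cluster, tier_cfg: TierConfig = TierConfig()) -> int:
    """Index of the cluster's key thumbnail under the MA_MAX rule.

    For clusters no larger than the moving-average window the key is simply
    the maximum-probability member. Otherwise the contiguous window of
    ``ma_window`` members with the highest mean probability is found (ties →
    earliest window) and the maximum-probability member inside it is returned
    (ties → earliest member).
    """
    probs = np.array([m.probability for m in cluster.members], dtype=float)
    n = len(probs)
    if n == 0:
        raise ValueError("empty cluster")
    w = tier_cfg.ma_window
    if n <= w:
        return int(np.argmax(probs))
    means = np.convolve(probs, np.ones(w) / w, mode="valid")
    start = int(np.argmax(means))  # argmax takes the earliest maximal window
    return start + int(np.argmax(probs[start : start + w]))


def rank_clusters(clusters: Sequence[Cluster]) -> list[Cluster]:
    """Display order: confidence desc, then larger cluster, then lower B-scan."""
    return sorted(
        clusters,
        key=lambda c: (
            -c.confidence,
            -len(c.members),
            min(m.bscan_index for m in c.members),
        ),
    )


def render_thumbnail(
    volume: MarginVolume, detection: Detection, patch_width: int = 188
) -> np.ndarray:
    """The detection's full-height patch resized (bilinear) to 188×188 float in [0, 1]."""
    n, h, w = volume.shape
    if not 0 <= detection.bscan_index < n:
        raise ValueError(f"bscan_index {detection.bscan_index} outside volume")
    if not 0 <= detection.x_start <= w - patch_width:
        raise ValueError(f"x_start {detection.x_start} outside valid range")
    patch = volume.bscans[detection.bscan_index, :, detection.x_start : detection.x_start + patch_width]
    patch = patch.astype(np.float64)
    if np.issubdtype(volume.bscans.dtype, np.integer):
        patch /= np.iinfo(volume.bscans.dtype).max
    return resize(patch, (patch_width, patch_width), order=1, anti_aliasing=True)


def detections_to_frame(
    clusters: Sequence[Cluster], discarded: Sequence[Detection]
) -> pd.DataFrame:
    """Flat per-detection table (CSV-ready): cluster id, key flag, tier."""
    rows = []
    for cid, cluster in enumerate(clusters):
        for i, d in enumerate(cluster.members):
            rows.append(
                {
                    "subject_id": d.subject_id, "margin_id": d.margin_id,
                    "bscan_index": d.bscan_index, "x_start": d.x_start,
                    "probability": d.probability, "tier": d.tier,
                    "cluster_id": cid, "is_key": i == cluster.key_index,
                }
            )
    for d in discarded:
        rows.append(
            {
                "subject_id": d.subject_id, "margin_id": d.margin_id,
                "bscan_index": d.bscan_index, "x_start": d.x_start,
                "probability": d.probability, "tier": d.tier,
                "cluster_id": -1, "is_key": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "margin_id", "bscan_index", "x_start",
                 "probability", "tier", "cluster_id", "is_key"],
    )
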