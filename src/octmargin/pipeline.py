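"""End-to-end orchestration: phantom batch → patches → CNN → report.

`run_demo` is the reference synthetic experiment: a batch of 12 phantom
margins (6 lesion-bearing), a subject-disjoint split, ~2,000 training
patches with annotation-dense augmentation, ~10 training epochs, margin
processing at the two-tier operating points, and the margin-level report.
Margins are deliberately smaller than clinical scans (24 B-scans × 940
columns) so the full experiment runs in minutes on one CPU core while
preserving the study's structure: lesions spanning ≥2 adjacent B-scans at
overlapping lateral positions, and patch-level class imbalance around 5%
before augmentation.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from octmargin import metrics as metrics_mod
from octmargin.cnn import (
    ArchConfig,
    TrainConfig,
    TrainHistory,
    build_model,
    patches_to_arrays,
    predict_patches,
    train,
)
from octmargin.cnn.model import PatchCNN
from octmargin.patchgen import (
    POSITIVE,
    Patch,
    PatchSpec,
    augment_annotations,
    extract_patches,
    grid_positions,
    label_patches,
)
from octmargin.phantom import AnnotationBox, MarginVolume, PhantomConfig, generate_margin
from octmargin.postproc import (
    Cluster,
    Detection,
    PatchPrediction,
    TierConfig,
    cluster_detections,
    detections_to_frame,
    threshold_detections,
)

__all__ = ["DemoSettings", "DemoResult", "run_demo", "process_margin", "demo_margin_configs"]


@dataclass(frozen=True)
class DemoSettings:
    """Study conditions of the synthetic end-to-end experiment."""

    n_margins: int = 12
    n_positive_margins: int = 6
    n_bscans: int = 24
    bscan_width: int = 940
    bscan_height: int = 420
    lesions_per_positive_margin: int = 3
    lesion_span_bscans: tuple[int, int] = (3, 5)
    lesion_width_px: tuple[int, int] = (120, 180)
    lesion_height_px: tuple[int, int] = (90, 150)
    epochs: int = 10
    fractions: dict = field(
        default_factory=lambda: {"train": 0.5, "val": 1.0 / 6.0, "test": 1.0 / 3.0}
    )


@dataclass
class DemoResult:
    settings: DemoSettings
    seed: int
    split: dict[str, list[str]]
    history: TrainHistory
    model: PatchCNN
    n_train_patches: int
    n_val_patches: int
    n_test_patches: int
    test_auroc: float
    test_auprc: float
    test_prevalence: float
    threshold_table: pd.DataFrame
    predictions: list[PatchPrediction]
    detections: dict[int, list[Detection]]          # tier -> detections (all margins)
    clusters: dict[int, dict[str, tuple[list[Cluster], list[Detection]]]]
    reports: dict[int, metrics_mod.MarginReport]
    positive_margins: list[str]
    runtime_s: float


def demo_margin_configs(settings: DemoSettings, seed: int) -> list[PhantomConfig]:
    """One PhantomConfig per margin; positive and negative margins interleave
    so every split stratum sees both classes. Child seeds derive from
    ``seed`` via a SeedSequence spawn."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(settings.n_margins)
    configs = []
    n_pos = 0
    for i in range(settings.n_margins):
        positive = (i % 2 == 0) and n_pos < settings.n_positive_margins
        if positive:
            n_pos += 1
        configs.append(
            PhantomConfig(
                n_bscans=settings.n_bscans,
                bscan_height=settings.bscan_height,
                bscan_width=settings.bscan_width,
                n_lesions=settings.lesions_per_positive_margin if positive else 0,
                lesion_span_bscans=settings.lesion_span_bscans,
                lesion_width_px=settings.lesion_width_px,
                lesion_height_px=settings.lesion_height_px,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
                subject_id=f"S{i:03d}",
                margin_id=f"M{i:03d}",
            )
        )
    return configs


def process_margin(
    model: PatchCNN,
    volume: MarginVolume,
    labeled: Sequence[Patch],
    spec: PatchSpec = PatchSpec(),
    tier_cfg: TierConfig = TierConfig(),
    batch_size: int = 64,
) -> tuple[list[PatchPrediction], dict[int, tuple[list[Cluster], list[Detection]]]]:
    """Predict one margin's grid patches and post-process both tiers.

    Returns the per-patch predictions (carrying ground-truth labels) and, per
    tier, the clusters and discarded singletons of that tier's detections.
    """
    starts = grid_positions(volume.shape[2], spec)
    col_of = {int(x): i for i, x in enumerate(starts)}
    probs = predict_patches(model, list(labeled), batch_size=batch_size)
    predictions = [
        PatchPrediction(
            subject_id=p.subject_id,
            margin_id=p.margin_id,
            bscan_index=p.bscan_index,
            grid_col_index=col_of[p.x_start],
            x_start=p.x_start,
            probability=float(prob),
            label=p.label,
        )
        for p, prob in zip(labeled, probs)
    ]
    out: dict[int, tuple[list[Cluster], list[Detection]]] = {}
    detections = threshold_detections(predictions, tier_cfg)
    out[1] = cluster_detections(detections, tier_cfg)
    tier2 = [d for d in detections if d.tier == 2]
    out[2] = cluster_detections(tier2, tier_cfg)
    return predictions, out


def run_demo(
    seed: int = 0,
    settings: DemoSettings = DemoSettings(),
    outdir: str | Path | None = None,
    spec: PatchSpec = PatchSpec(),
    arch: ArchConfig = ArchConfig(),
    tier_cfg: TierConfig = TierConfig(),
) -> DemoResult:
    """Run the full synthetic experiment; optionally write report files."""
    t0 = time.time()
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))

    configs = demo_margin_configs(settings, seed)
    volumes: dict[str, MarginVolume] = {}
    annotations: dict[str, list[AnnotationBox]] = {}
    labeled: dict[str, list[Patch]] = {}
    for cfg in configs:
        vol, ann = generate_margin(cfg)
        volumes[cfg.margin_id] = vol
        annotations[cfg.margin_id] = ann
        labeled[cfg.margin_id] = label_patches(extract_patches(vol, spec), ann)

    subject_table = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in configs],
            "margin_id": [c.margin_id for c in configs],
            "is_positive": [c.n_lesions > 0 for c in configs],
        }
    )
    split = metrics_mod.split_subjects(subject_table, settings.fractions, seed=seed)

    def _patches(margin_ids: Sequence[str], augment: bool) -> list[Patch]:
        out: list[Patch] = []
        for m in margin_ids:
            out.extend(labeled[m])
            if augment:
                out.extend(augment_annotations(annotations[m], volumes[m], spec))
        return out

    train_patches = _patches(split["train"], augment=True)
    val_patches = _patches(split["val"], augment=True)
    test_patches = _patches(split["test"], augment=False)

    model = build_model(arch, seed=rng_seed)
    best, history = train(
        model,
        train_patches,
        val_patches,
        TrainConfig(epochs=settings.epochs, seed=rng_seed),
    )

    x_te, y_te = patches_to_arrays(test_patches)
    test_probs = predict_patches(best, x_te)
    auroc, auprc, prevalence = metrics_mod.roc_pr(y_te, test_probs)
    table = metrics_mod.threshold_table(y_te, test_probs)

    predictions: list[PatchPrediction] = []
    clusters: dict[int, dict[str, tuple[list[Cluster], list[Detection]]]] = {1: {}, 2: {}}
    for m in sorted(volumes):
        preds, per_tier = process_margin(best, volumes[m], labeled[m], spec, tier_cfg)
        predictions.extend(preds)
        clusters[1][m] = per_tier[1]
        clusters[2][m] = per_tier[2]

    all_detections = threshold_detections(predictions, tier_cfg)
    detections = {1: all_detections, 2: [d for d in all_detections if d.tier == 2]}
    margin_ids = sorted(volumes)
    reports = {
        tier: metrics_mod.margin_report(
            margin_ids,
            predictions,
            detections[tier],
            [c for m in margin_ids for c in clusters[tier][m][0]],
            tier_cfg,
            tier=tier,
        )
        for tier in (1, 2)
    }

    result = DemoResult(
        settings=settings,
        seed=seed,
        split=split,
        history=history,
        model=best,
        n_train_patches=len(train_patches),
        n_val_patches=len(val_patches),
        n_test_patches=len(test_patches),
        test_auroc=auroc,
        test_auprc=auprc,
        test_prevalence=prevalence,
        threshold_table=table,
        predictions=predictions,
        detections=detections,
        clusters=clusters,
        reports=reports,
        positive_margins=[c.margin_id for c in configs if c.n_lesions > 0],
        runtime_s=time.time() - t0,
    )
    if outdir is not None:
        write_demo_report(result, outdir, volumes=volumes)
    return result


def write_demo_report(
    result: DemoResult,
    outdir: str | Path,
    volumes: dict[str, MarginVolume] | None = None,
    max_thumbnails: int = 12,
) -> None:
    from octmargin.postproc import rank_clusters, render_thumbnail

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if volumes is not None:
        from PIL import Image

        for tier in (1, 2):
            ranked = rank_clusters(
                [c for cl, _ in result.clusters[tier].values() for c in cl]
            )
            tdir = outdir / f"thumbnails_tier{tier}"
            tdir.mkdir(exist_ok=True)
            for rank, cluster in enumerate(ranked[:max_thumbnails]):
                key = cluster.key
                thumb = render_thumbnail(volumes[key.margin_id], key)
                name = f"rank{rank:02d}_{key.margin_id}_b{key.bscan_index:04d}.png"
                Image.fromarray((thumb * 255).astype(np.uint8)).save(tdir / name)
    result.threshold_table.to_csv(outdir / "threshold_table.csv", index=False)
    for tier in (1, 2):
        rep = result.reports[tier]
        pd.Series(rep.to_dict()).to_csv(outdir / f"margin_report_tier{tier}.csv", header=False)
        frames = [
            detections_to_frame(cl, disc) for cl, disc in result.clusters[tier].values()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"detections_tier{tier}.csv", index=False
        )
    manifest = {
        "seed": result.seed,
        "settings": dataclasses.asdict(result.settings),
        "split": result.split,
        "selected_epoch": result.history.selected_epoch,
        "test_auroc": result.test_auroc,
        "test_auprc": result.test_auprc,
        "test_prevalence": result.test_prevalence,
        "runtime_s": result.runtime_s,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
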