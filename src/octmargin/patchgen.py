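"""Overlapping-patch decomposition of B-scans, labeling, and augmentation.

Every B-scan is cut into full-height 420×188 windows sliding laterally with a
half-width stride (round(0.5 × 188) = 94 px), giving ~30 windows on a
2400-column scan. Patches overlapping a suspicious annotation are labeled
positive; around each annotation five additional translated patches are
extracted at one fifth of the stride (19 px) to densify the rare positive
class. All coordinates are 0-based, intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from octmargin.phantom import SUSPICIOUS, AnnotationBox, MarginVolume

__all__ = [
    "PatchSpec",
    "Patch",
    "grid_positions",
    "extract_patches",
    "label_patches",
    "augment_positive",
    "augment_annotations",
    "patch_budget",
    "patch_name",
]

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: size, grid stride, augmentation spacing, edge policy."""

    patch_height: int = 420
    patch_width: int = 188
    step_fraction: float = 0.5
    augment_step_divisor: int = 5
    edge_policy: str = "align_last"  # {"pad", "align_last", "drop"}

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step_fraction must be in (0, 1]")
        if self.patch_height < 1 or self.patch_width < 1:
            raise ValueError("patch dimensions must be positive")
        if self.augment_step_divisor < 1:
            raise ValueError("augment_step_divisor must be >= 1")
        if self.edge_policy not in ("pad", "align_last", "drop"):
            raise ValueError("edge_policy must be 'pad', 'align_last' or 'drop'")

    @property
    def stride(self) -> int:
        """Lateral grid stride in pixels: round(step_fraction × patch_width)."""
        return int(round(self.step_fraction * self.patch_width))

    @property
    def augment_step(self) -> int:
        """Spacing of the translated positive patches: round(stride / divisor)."""
        return int(round(self.stride / self.augment_step_divisor))


@dataclass
class Patch:
    subject_id: str
    margin_id: str
    bscan_index: int
    x_start: int
    pixels: np.ndarray  # (patch_height, patch_width) grayscale view
    label: str = UNLABELED
    origin: str = "grid"  # {"grid", "augmented"}

    @property
    def x_end(self) -> int:
        return self.x_start + self.pixels.shape[1]


def grid_positions(bscan_width: int, spec: PatchSpec = PatchSpec()) -> np.ndarray:
    """Strictly increasing patch start columns covering one B-scan.

    Starts are multiples of the stride with the window inside the scan.
    Border handling: ``align_last`` appends a final start at
    ``bscan_width − patch_width`` when not already on the grid so the right
    border is covered; ``pad`` instead keeps the next on-grid start whose
    window sticks out (the extracted patch is zero-padded on the right);
    ``drop`` leaves the border uncovered.
    """
    if bscan_width < spec.patch_width:
        raise ValueError(
            f"bscan_width {bscan_width} smaller than patch_width {spec.patch_width}"
        )
    last = bscan_width - spec.patch_width
    starts = list(range(0, last + 1, spec.stride))
    if spec.edge_policy == "align_last" and starts[-1] != last:
        starts.append(last)
    elif spec.edge_policy == "pad" and starts[-1] != last:
        starts.append(starts[-1] + spec.stride)  # overhangs; padded at extraction
    return np.asarray(starts, dtype=int)


def patch_budget(n_margins: int, n_bscans_per_margin: int, patches_per_bscan: int = 30) -> int:
    """Accounting helper: total grid patches for a subject's margin scans.

    Six margins of ~400 B-scans at ~30 patches per B-scan give 72,000 patches.
    """
    return n_margins * n_bscans_per_margin * patches_per_bscan


def extract_patches(volume: MarginVolume, spec: PatchSpec = PatchSpec()) -> list[Patch]:
    """One unlabeled grid patch per (B-scan, grid position).

    Pixel arrays are views into the volume (no copy); full B-scan height is
    required to match ``patch_height``.
    """
    n, h, w = volume.shape
    if h != spec.patch_height:
        raise ValueError(f"B-scan height {h} != patch_height {spec.patch_height}")
    starts = grid_positions(w, spec)
    patches = []
    for b in range(n):
        for x in starts:
            if x + spec.patch_width <= w:
                pixels = volume.bscans[b, :, x : x + spec.patch_width]
            else:  # pad policy: right-pad the overhanging border window
                pixels = np.zeros((h, spec.patch_width), dtype=volume.bscans.dtype)
                pixels[:, : w - x] = volume.bscans[b, :, x:]
            patches.append(
                Patch(
                    subject_id=volume.subject_id,
                    margin_id=volume.margin_id,
                    bscan_index=b,
                    x_start=int(x),
                    pixels=pixels,
                )
            )
    return patches


def _column_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def label_patches(
    patches: Iterable[Patch],
    annotations: Sequence[AnnotationBox],
    overlap_threshold: float = 0.5,
) -> list[Patch]:
    """Assign positive/negative labels from suspicious annotation boxes.

    A patch is positive iff, on its own B-scan, some suspicious box's column
    interval is overlapped by at least ``overlap_threshold`` of the box width.
    Idempotent and order-independent; empty annotations give all negatives.
    """
    by_bscan: dict[int, list[AnnotationBox]] = {}
    for a in annotations:
        if a.label == SUSPICIOUS:
            by_bscan.setdefault(a.bscan_index, []).append(a)

    labeled = []
    for p in patches:
        label = NEGATIVE
        for a in by_bscan.get(p.bscan_index, ()):
            if _column_overlap(p.x_start, p.x_end, a.x_start, a.x_end) >= overlap_threshold * a.width:
                label = POSITIVE
                break
        labeled.append(replace(p, label=label))
    return labeled


def augment_positive(
    annotation: AnnotationBox,
    volume: MarginVolume,
    spec: PatchSpec = PatchSpec(),
) -> list[Patch]:
    """Five translated positive patches centered on one suspicious annotation.

    Starts are symmetric about the annotation center at the augmentation
    spacing (19 px for the default 94-px stride), clipped to the valid start
    range; clipping may merge starts, in which case duplicates are dropped and
    fewer than five patches are returned.
    """
    if annotation.label != SUSPICIOUS:
        raise ValueError("augmentation is defined for suspicious annotations only")
    _, h, w = volume.shape
    if h != spec.patch_height:
        raise ValueError(f"B-scan height {h} != patch_height {spec.patch_height}")

    step = spec.augment_step
    center = (annotation.x_start + annotation.x_end) / 2.0
    c = int(round(center - spec.patch_width / 2.0))
    lo, hi = 0, w - spec.patch_width
    starts = []
    for k in (-2, -1, 0, 1, 2):
        s = min(max(c + k * step, lo), hi)
        if s not in starts:
            starts.append(s)

    return [
        Patch(
            subject_id=volume.subject_id,
            margin_id=volume.margin_id,
            bscan_index=annotation.bscan_index,
            x_start=s,
            pixels=volume.bscans[annotation.bscan_index, :, s : s + spec.patch_width],
            label=POSITIVE,
            origin="augmented",
        )
        for s in sorted(starts)
    ]


def augment_annotations(
    annotations: Sequence[AnnotationBox],
    volume: MarginVolume,
    spec: PatchSpec = PatchSpec(),
) -> list[Patch]:
    """Translated positive patches for every suspicious annotation of a margin."""
    out: list[Patch] = []
    for a in annotations:
        if a.label == SUSPICIOUS:
            out.extend(augment_positive(a, volume, spec))
    return out


def patch_name(patch: Patch) -> str:
    """Distinct file-name stem: ``{subject}_{margin}_{bscan:04d}_{x:05d}_{origin}``."""
    return (
        f"{patch.subject_id}_{patch.margin_id}_"
        f"{patch.bscan_index:04d}_{patch.x_start:05d}_{patch.origin}"
    )
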