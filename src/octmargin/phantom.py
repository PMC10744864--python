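"""Synthetic wide-field OCT margin phantoms with known lesion ground truth.

A margin scan is an ordered stack of grayscale B-scans (depth × lateral
position). Real scans show bright horizontal tissue layering modulated by
multiplicative speckle; suspicious lesions (DCIS/IDC-like foci) appear as
compact hyper-intense regions with a distinct granular texture that persist
across several adjacent B-scans at overlapping lateral positions. The phantom
reproduces exactly those statistical properties — geometry, cross-scan
adjacency, contrast and extreme class imbalance — not the interferometric
physics of OCT, so downstream patching / classification / clustering stages
can be exercised without any clinical data.

Coordinates are 0-based with half-open intervals throughout the package:
an :class:`AnnotationBox` covers columns ``x_start <= x < x_end`` and rows
``y_start <= y < y_end`` on B-scan ``bscan_index``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "MarginVolume",
    "AnnotationBox",
    "generate_margin",
    "write_margin",
    "read_margin",
]

SUSPICIOUS = "suspicious"
NON_SUSPICIOUS = "non_suspicious"


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic margin.

    The defaults mirror a typical clinical margin scan: ~400 B-scans of
    420 rows × 2400 columns at 8 bit. ``seed`` fully determines the output.
    """

    n_bscans: int = 400
    bscan_height: int = 420
    bscan_width: int = 2400
    n_lesions: int = 3
    lesion_span_bscans: tuple[int, int] = (3, 6)   # inclusive range, min >= 2
    lesion_width_px: tuple[int, int] = (120, 220)
    lesion_height_px: tuple[int, int] = (80, 160)
    lesion_contrast: float = 80.0                  # mean intensity offset, 8-bit units
    lesion_column_jitter: int = 12                 # per-B-scan lateral wobble, px
    texture_params: dict = field(
        default_factory=lambda: {
            "n_layers": 6,
            "layer_contrast": 15.0,
            "base_intensity": 105.0,
            "speckle_sigma": 1.5,
            "speckle_strength": 0.22,
        }
    )
    noise_sigma: float = 4.0
    bit_depth: int = 8
    seed: int = 0
    subject_id: str = "S000"
    margin_id: str = "M00"

    def __post_init__(self) -> None:
        if self.n_bscans < 1:
            raise ValueError("n_bscans must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        lo, hi = self.lesion_span_bscans
        if lo < 2 or hi < lo:
            raise ValueError("lesion_span_bscans must be an increasing range with min >= 2")
        if self.n_lesions > 0 and hi > self.n_bscans:
            raise ValueError(
                f"lesion span up to {hi} B-scans cannot fit in a {self.n_bscans}-B-scan volume"
            )
        wlo, whi = self.lesion_width_px
        if wlo < 1 or whi < wlo or whi > self.bscan_width:
            raise ValueError("lesion_width_px range does not fit inside the B-scan")
        hlo, hhi = self.lesion_height_px
        if hlo < 1 or hhi < hlo or hhi > self.bscan_height:
            raise ValueError("lesion_height_px range does not fit inside the B-scan")
        if self.lesion_column_jitter < 0 or 2 * self.lesion_column_jitter >= wlo:
            raise ValueError(
                "lesion_column_jitter must be < half the minimum lesion width "
                "so one lesion's column intervals always overlap"
            )

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class MarginVolume:
    """Ordered stack of grayscale B-scans for one surgical margin."""

    subject_id: str
    margin_id: str
    bscans: np.ndarray  # (n_bscans, height, width), uint8 or uint16

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans)
        if self.bscans.ndim != 3:
            raise ValueError("bscans must be a (n_bscans, height, width) array")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bscans.shape


@dataclass(frozen=True)
class AnnotationBox:
    """A labeled rectangular region on one B-scan (half-open intervals)."""

    bscan_index: int
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    label: str = SUSPICIOUS

    def __post_init__(self) -> None:
        if self.x_end <= self.x_start:
            raise ValueError(f"empty column interval [{self.x_start}, {self.x_end})")
        if self.y_end <= self.y_start:
            raise ValueError(f"empty row interval [{self.y_start}, {self.y_end})")
        if self.bscan_index < 0 or self.x_start < 0 or self.y_start < 0:
            raise ValueError("coordinates must be non-negative")
        if self.label not in (SUSPICIOUS, NON_SUSPICIOUS):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def width(self) -> int:
        return self.x_end - self.x_start


def _background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Layered, speckled background for the whole volume, float32 in intensity units."""
    tp = cfg.texture_params
    n, h, w = cfg.n_bscans, cfg.bscan_height, cfg.bscan_width

    # Smooth horizontal layers: piecewise-constant intensity by depth, blurred.
    n_layers = int(tp.get("n_layers", 6))
    bounds = np.sort(rng.integers(0, h, size=max(n_layers - 1, 1)))
    levels = tp.get("base_intensity", 110.0) + tp.get("layer_contrast", 30.0) * rng.standard_normal(n_layers)
    profile = np.empty(h, dtype=np.float32)
    prev = 0
    for i, b in enumerate(list(bounds) + [h]):
        profile[prev:b] = levels[i]
        prev = b
    profile = ndimage.gaussian_filter1d(profile, sigma=12.0)

    # Correlated multiplicative speckle, independent per B-scan; generated
    # slice by slice so a clinical-size volume (400 x 420 x 2400) never
    # materializes gigabyte temporaries.
    strength = float(tp.get("speckle_strength", 0.22))
    sigma = float(tp.get("speckle_sigma", 1.5))
    vol = np.empty((n, h, w), dtype=np.float32)
    for i in range(n):
        noise = rng.standard_normal((h, w)).astype(np.float32)
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
        noise /= max(noise.std(), 1e-8)
        bscan = profile[:, None] * (1.0 + strength * noise)
        if cfg.noise_sigma > 0:
            bscan += cfg.noise_sigma * rng.standard_normal((h, w)).astype(np.float32)
        vol[i] = bscan
    return vol


def _place_lesions(
    cfg: PhantomConfig, rng: np.random.Generator
) -> list[tuple[int, int, int, int, int, int]]:
    """Sample non-overlapping lesion geometries.

    Returns tuples (b0, b1, x0, x1, y0, y1): B-scan run [b0, b1) and the
    shared column/row box. Raises ValueError when geometry cannot fit.
    """
    # Global restarts: an unlucky early placement can block the rest, so the
    # whole arrangement is resampled rather than giving up.
    for _restart in range(50):
        placed: list[tuple[int, int, int, int, int, int]] = []
        for _ in range(cfg.n_lesions):
            for _attempt in range(100):
                span = int(rng.integers(cfg.lesion_span_bscans[0], cfg.lesion_span_bscans[1] + 1))
                width = int(rng.integers(cfg.lesion_width_px[0], cfg.lesion_width_px[1] + 1))
                height = int(rng.integers(cfg.lesion_height_px[0], cfg.lesion_height_px[1] + 1))
                if span > cfg.n_bscans or width > cfg.bscan_width or height > cfg.bscan_height:
                    continue
                b0 = int(rng.integers(0, cfg.n_bscans - span + 1))
                x0 = int(rng.integers(0, cfg.bscan_width - width + 1))
                y0 = int(rng.integers(0, cfg.bscan_height - height + 1))
                cand = (b0, b0 + span, x0, x0 + width, y0, y0 + height)
                if all(
                    cand[1] + 1 <= p[0] or p[1] + 1 <= cand[0]  # B-scan-disjoint with 1 gap
                    or cand[3] + 188 <= p[2] or p[3] + 188 <= cand[2]  # or laterally far apart
                    for p in placed
                ):
                    placed.append(cand)
                    break
            else:
                break  # this arrangement dead-ended; restart from scratch
        if len(placed) == cfg.n_lesions:
            return placed
    raise ValueError(
        "could not place the requested lesions without overlap; "
        "reduce n_lesions or lesion geometry ranges"
    )


def generate_margin(config: PhantomConfig) -> tuple[MarginVolume, list[AnnotationBox]]:
    """Generate one synthetic margin and its ground-truth annotation boxes.

    Each lesion spans a contiguous run of >= 2 B-scans at an identical column
    interval (so a perfect detector yields adjacent detections that satisfy
    the clustering assumption) and is rendered as a hyper-intense ellipse with
    high-frequency granular texture. One suspicious box is emitted per lesion
    per B-scan it touches.
    """
    rng = np.random.default_rng(config.seed)
    vol = _background(config, rng)
    annotations: list[AnnotationBox] = []

    jitter = config.lesion_column_jitter
    for (b0, b1, x0, x1, y0, y1) in _place_lesions(config, rng):
        h, w = y1 - y0, x1 - x0
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        ellipse = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0
        for b in range(b0, b1):
            # Per-B-scan lateral wobble (biological cross-sections are not
            # perfectly aligned); bounded by jitter < w/2 so the column
            # intervals of one lesion always pairwise overlap.
            dx = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            dx = max(-x0, min(dx, config.bscan_width - x1))
            # Granular second-order texture distinguishes lesion from smooth speckle.
            grain = rng.standard_normal((h, w)).astype(np.float32)
            bump = (config.lesion_contrast * (1.0 + 0.25 * grain)) * ellipse
            vol[b, y0:y1, x0 + dx : x1 + dx] += bump
            annotations.append(
                AnnotationBox(
                    bscan_index=b, x_start=x0 + dx, x_end=x1 + dx,
                    y_start=y0, y_end=y1,
                )
            )

    vol = np.clip(vol, 0, config.intensity_max).astype(config.dtype)
    volume = MarginVolume(config.subject_id, config.margin_id, vol)
    return volume, annotations


# ---------------------------------------------------------------------------
# I/O: per-slice TIFF/PNG + annotations.csv + manifest.json

_ANNOT_COLUMNS = [
    "subject_id",
    "margin_id",
    "bscan_index",
    "x_start",
    "x_end",
    "y_start",
    "y_end",
    "label",
]


def annotations_to_frame(
    volume: MarginVolume, annotations: Sequence[AnnotationBox]
) -> pd.DataFrame:
    rows = [
        {
            "subject_id": volume.subject_id,
            "margin_id": volume.margin_id,
            "bscan_index": a.bscan_index,
            "x_start": a.x_start,
            "x_end": a.x_end,
            "y_start": a.y_start,
            "y_end": a.y_end,
            "label": a.label,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=_ANNOT_COLUMNS)


def write_margin(
    volume: MarginVolume,
    annotations: Sequence[AnnotationBox],
    directory: str | Path,
    image_format: str = "tif",
    config: PhantomConfig | None = None,
) -> Path:
    """Write per-slice images, ``annotations.csv`` and ``manifest.json``.

    Returns the manifest path. ``read_margin`` of the directory restores the
    volume and annotations exactly.
    """
    if image_format not in ("tif", "png"):
        raise ValueError("image_format must be 'tif' or 'png'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files = []
    for i in range(volume.n_bscans):
        name = f"bscan_{i:04d}.{image_format}"
        path = directory / name
        if image_format == "tif":
            tifffile.imwrite(path, volume.bscans[i])
        else:
            Image.fromarray(volume.bscans[i]).save(path)
        files.append(name)

    annotations_to_frame(volume, annotations).to_csv(directory / "annotations.csv", index=False)

    checksum = hashlib.sha1(np.ascontiguousarray(volume.bscans).tobytes()).hexdigest()
    manifest = {
        "subject_id": volume.subject_id,
        "margin_id": volume.margin_id,
        "n_bscans": volume.n_bscans,
        "bscan_height": int(volume.bscans.shape[1]),
        "bscan_width": int(volume.bscans.shape[2]),
        "dtype": str(volume.bscans.dtype),
        "image_format": image_format,
        "files": files,
        "pixel_sha1": checksum,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_margin(directory: str | Path) -> tuple[MarginVolume, list[AnnotationBox]]:
    """Read a margin directory written by :func:`write_margin`.

    Raises ``FileNotFoundError`` naming the missing piece when the manifest or
    any listed slice is absent, and ``ValueError`` on invalid annotations.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())

    missing = [f for f in manifest["files"] if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing B-scan slice(s): {', '.join(missing)}")

    slices = []
    for name in manifest["files"]:
        path = directory / name
        if manifest["image_format"] == "tif":
            slices.append(tifffile.imread(path))
        else:
            slices.append(np.asarray(Image.open(path)))
    bscans = np.stack(slices, axis=0)

    volume = MarginVolume(manifest["subject_id"], manifest["margin_id"], bscans)

    annot_path = directory / "annotations.csv"
    if not annot_path.exists():
        raise FileNotFoundError(f"missing annotation table: {annot_path}")
    table = pd.read_csv(annot_path)
    annotations = []
    for row in table.itertuples(index=False):
        box = AnnotationBox(
            bscan_index=int(row.bscan_index),
            x_start=int(row.x_start),
            x_end=int(row.x_end),
            y_start=int(row.y_start),
            y_end=int(row.y_end),
            label=str(row.label),
        )
        if box.bscan_index >= volume.n_bscans:
            raise ValueError(f"annotation bscan_index {box.bscan_index} outside volume")
        if box.x_end > volume.bscans.shape[2] or box.y_end > volume.bscans.shape[1]:
            raise ValueError("annotation box extends outside the B-scan")
        annotations.append(box)
    return volume, annotations
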