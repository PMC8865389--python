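"""Slide preparation: tissue-slice extraction, patch tiling, scale sets.

A digitized skin biopsy usually carries several physically separate tissue
sections ("slices") on a bright background. The pipeline segments them with
Otsu thresholding on the luma channel followed by morphological cleanup
(opening, closing, hole filling), keeps each connected component as one
:class:`TissueSlice`, and tiles each slice crop into a square grid of ``m``
non-overlapping patches per input scale.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import resize
from skimage.util import img_as_float

logger = logging.getLogger(__name__)

#: Relative resize factors of the default input scales. The tags mirror the
#: microscope zoom levels they emulate; 10x is the base resolution.
DEFAULT_SCALE_FACTORS: dict[str, float] = {"7.5x": 0.75, "10x": 1.0, "12.5x": 1.25}

#: Patch counts per scale: fewer patches at coarser zoom so that individual
#: patch footprints stay comparable in tissue area.
DEFAULT_M_PER_SCALE: dict[str, int] = {"7.5x": 25, "10x": 49, "12.5x": 81}

#: Severity-ordered diagnostic categories (index 1..4).
CLASS_NAMES: tuple[str, ...] = ("MMD", "MIS", "pT1a", "pT1b")


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open box [x0, x1) x [y0, y1), 0-based pixels."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1"):
            object.__setattr__(self, name, int(getattr(self, name)))

    def scaled(self, factor: float) -> "Box":
        return Box(
            math.floor(self.x0 * factor),
            math.floor(self.y0 * factor),
            math.ceil(self.x1 * factor),
            math.ceil(self.y1 * factor),
        )

    def clipped(self, width: int, height: int) -> "Box":
        return Box(
            max(0, min(self.x0, width)),
            max(0, min(self.y0, height)),
            max(0, min(self.x1, width)),
            max(0, min(self.y1, height)),
        )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def as_list(self) -> list[int]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass
class SlideRecord:
    """One whole slide: images per scale tag, diagnostic class, ROI boxes.

    ``class_index`` is 1-based and severity ordered (1 = MMD ... 4 = pT1b).
    ROI boxes are given in base-scale pixel coordinates.
    """

    slide_id: str
    images: dict[str, np.ndarray]
    class_index: int
    roi_boxes: list[Box] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.class_index <= len(CLASS_NAMES):
            raise ValueError(f"class_index must be in 1..{len(CLASS_NAMES)}")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_index - 1]


@dataclass
class TissueSlice:
    """One connected tissue region with its mask, bbox and per-scale crops."""

    slice_id: str
    mask: np.ndarray  # bool, full base-image frame
    bbox: Box  # tight bounds of mask, base scale
    crops: dict[str, np.ndarray] = field(default_factory=dict)
    has_roi: bool = False
    label: object = None  # LabelVector, attached by the labeling stage
    area: int = 0


@dataclass
class PatchGrid:
    """Row-major square grid of ``m`` equal, non-overlapping patches."""

    patches: np.ndarray  # (m, ph, pw, 3)
    grid_shape: tuple[int, int]
    scale_tag: str = ""

    @property
    def m(self) -> int:
        return self.patches.shape[0]

    def reassemble(self) -> np.ndarray:
        """Stitch the patches back into the padded crop (row-major order)."""
        rows, cols = self.grid_shape
        m, ph, pw, ch = self.patches.shape
        out = self.patches.reshape(rows, cols, ph, pw, ch)
        return out.transpose(0, 2, 1, 3, 4).reshape(rows * ph, cols * pw, ch)


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = img_as_float(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    return img


def extract_tissue_slices(
    image: np.ndarray,
    min_area_fraction: float = 0.001,
    kernel_radius: int | None = None,
    consolidation_radius: int | None = None,
    slide_id: str = "slide",
) -> list[TissueSlice]:
    """Segment tissue slices from a bright-background slide image.

    Otsu's threshold on the luma channel separates (darker) tissue from the
    bright background; morphological opening then closing with a small disk,
    then hole filling, cleans the mask. A second, larger closing (the
    contour-consolidation stage) reconnects fragments of one section that
    pale tissue regions may have severed — its radius must stay below half
    the smallest expected gap between distinct sections. Each surviving
    connected component becomes one slice, sorted by descending area.
    Components smaller than ``min_area_fraction`` of the image area are
    dropped. If nothing survives, an empty list is returned and a warning is
    logged.
    """
    gray = _to_gray(image)
    height, width = gray.shape
    if gray.max() == gray.min():
        logger.warning("no tissue found on %s: image is uniform", slide_id)
        return []
    thresh = threshold_otsu(gray)
    fg = gray < thresh  # tissue is darker than background

    if kernel_radius is None:
        kernel_radius = max(3, int(round(0.002 * min(height, width))))
    selem = morphology.disk(kernel_radius)
    fg = morphology.opening(fg, selem)
    fg = morphology.closing(fg, selem)
    fg = ndi.binary_fill_holes(fg)
    if consolidation_radius is None:
        consolidation_radius = max(10, int(round(0.01 * min(height, width))))
    if consolidation_radius > 0:
        fg = morphology.closing(fg, morphology.disk(consolidation_radius))
        fg = ndi.binary_fill_holes(fg)

    labeled = measure.label(fg, connectivity=2)
    props = measure.regionprops(labeled)
    min_area = min_area_fraction * height * width
    props = [p for p in props if p.area >= min_area]
    if not props:
        logger.warning("no tissue component above %.0f px on %s", min_area, slide_id)
        return []
    props.sort(key=lambda p: p.area, reverse=True)

    slices = []
    for i, p in enumerate(props):
        mask = labeled == p.label
        y0, x0, y1, x1 = p.bbox
        slices.append(
            TissueSlice(
                slice_id=f"{slide_id}_s{i}",
                mask=mask,
                bbox=Box(x0, y0, x1, y1),
                area=int(p.area),
            )
        )
    return slices


def mark_roi_slices(slices: list[TissueSlice], roi_boxes: list[Box]) -> None:
    """Set ``has_roi`` on every slice whose mask intersects an ROI box."""
    for sl in slices:
        sl.has_roi = False
        h, w = sl.mask.shape
        for box in roi_boxes:
            b = box.clipped(w, h)
            if b.width > 0 and b.height > 0 and sl.mask[b.y0 : b.y1, b.x0 : b.x1].any():
                sl.has_roi = True
                break


def attach_scale_crops(
    slices: list[TissueSlice],
    images: dict[str, np.ndarray],
    scale_factors: dict[str, float] = DEFAULT_SCALE_FACTORS,
) -> None:
    """Crop every slice from every scale image by rescaling its base bbox."""
    for sl in slices:
        for tag, factor in scale_factors.items():
            img = images[tag]
            h, w = img.shape[:2]
            b = sl.bbox.scaled(factor).clipped(w, h)
            sl.crops[tag] = img[b.y0 : b.y1, b.x0 : b.x1]


def build_scale_set(
    base_image: np.ndarray,
    scale_factors: dict[str, float] = DEFAULT_SCALE_FACTORS,
) -> dict[str, np.ndarray]:
    """Resample the base image to each configured relative magnification."""
    out = {}
    for tag, factor in scale_factors.items():
        if factor <= 0:
            raise ValueError(f"scale factor for {tag!r} must be positive")
        if factor == 1.0:
            out[tag] = base_image.copy()
            continue
        h, w = base_image.shape[:2]
        new_shape = (round(h * factor), round(w * factor))
        resized = resize(
            img_as_float(base_image),
            new_shape + base_image.shape[2:],
            order=1,
            anti_aliasing=factor < 1.0,
            preserve_range=True,
        )
        if np.issubdtype(base_image.dtype, np.integer):
            resized = np.clip(np.round(resized * 255), 0, 255).astype(np.uint8)
        out[tag] = resized
    return out


def _median_border_color(crop: np.ndarray) -> np.ndarray:
    border = np.concatenate(
        [
            crop[0].reshape(-1, crop.shape[-1]),
            crop[-1].reshape(-1, crop.shape[-1]),
            crop[:, 0].reshape(-1, crop.shape[-1]),
            crop[:, -1].reshape(-1, crop.shape[-1]),
        ]
    )
    return np.median(border, axis=0)


def tile_patches(crop: np.ndarray, m: int, scale_tag: str = "") -> PatchGrid:
    """Cut a crop into a row-major sqrt(m) x sqrt(m) grid of equal patches.

    The crop is first padded (bottom/right) with its median border color to
    dimensions divisible by sqrt(m), so the patches tile it exactly.
    """
    side = math.isqrt(m)
    if side * side != m:
        raise ValueError(f"m={m} is not a perfect square")
    if crop.ndim == 2:
        crop = crop[..., None]
    h, w, ch = crop.shape
    ph = math.ceil(h / side)
    pw = math.ceil(w / side)
    pad_h, pad_w = side * ph - h, side * pw - w
    if pad_h or pad_w:
        fill = _median_border_color(crop)
        padded = np.empty((side * ph, side * pw, ch), dtype=crop.dtype)
        padded[:] = np.round(fill) if np.issubdtype(crop.dtype, np.integer) else fill
        padded[:h, :w] = crop
    else:
        padded = crop
    patches = (
        padded.reshape(side, ph, side, pw, ch)
        .transpose(0, 2, 1, 3, 4)
        .reshape(m, ph, pw, ch)
    )
    return PatchGrid(patches=patches, grid_shape=(side, side), scale_tag=scale_tag)


def prepare_slide(
    record: SlideRecord,
    scale_factors: dict[str, float] = DEFAULT_SCALE_FACTORS,
    base_tag: str = "10x",
    min_area_fraction: float = 0.001,
) -> list[TissueSlice]:
    """Full slide prep: segment slices, mark ROIs, attach per-scale crops."""
    slices = extract_tissue_slices(
        record.images[base_tag],
        min_area_fraction=min_area_fraction,
        slide_id=record.slide_id,
    )
    mark_roi_slices(slices, record.roi_boxes)
    attach_scale_crops(slices, record.images, scale_factors)
    return slices


def write_slice_manifest(slices: list[TissueSlice], path: str | Path) -> None:
    """Write the per-slice JSON manifest (slice_id, bbox, has_roi, area)."""
    entries = [
        {
            "slice_id": sl.slice_id,
            "bbox": sl.bbox.as_list(),
            "has_roi": bool(sl.has_roi),
            "area": int(sl.area),
        }
        for sl in slices
    ]
    Path(path).write_text(json.dumps(entries, indent=1))
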