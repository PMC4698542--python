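"""Band densitometry for Western-blot images.

A band is quantified from a rectangular region of interest (ROI) by
subtracting a locally estimated background, integrating the residual
pixel intensity over the ROI, and dividing by the ROI width in pixels.
The width division controls for variations in lane width, so bands of
different widths carrying the same total signal yield the same density.

Coordinates are 0-based and ROI extents are half-open on both axes:
an ROI covers columns ``x0 .. x0+width-1`` and rows ``y0 .. y0+height-1``.
Pixel values are used as stored; no gamma or depth rescaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandROI",
    "BandMeasurement",
    "estimate_background",
    "quantify_band",
    "quantify_blot",
    "read_image",
    "read_roi_table",
    "write_roi_table",
    "measurements_to_frame",
]

ROI_COLUMNS = ("blot_id", "protein", "lane_id", "x0", "y0", "width", "height")


@dataclass(frozen=True)
class BandROI:
    """Rectangular band region: 0-based top-left corner plus half-open extents."""

    blot_id: str
    protein: str
    lane_id: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"ROI {self.blot_id}/{self.protein}/{self.lane_id}: "
                f"width and height must be >= 1, got {self.width}x{self.height}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(
                f"ROI {self.blot_id}/{self.protein}/{self.lane_id}: "
                f"negative origin ({self.x0}, {self.y0})"
            )

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def overlaps(self, other: "BandROI") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class BandMeasurement:
    """One quantified band: identity plus background-corrected, width-normalized density."""

    blot_id: str
    lane_id: str
    animal_id: str
    group: str
    protein: str
    raw_density: float
    background_level: float

    def __post_init__(self) -> None:
        if self.raw_density < 0:
            raise ValueError("raw_density must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")


def _check_inside(image: np.ndarray, roi: BandROI) -> None:
    h, w = image.shape
    if roi.x1 > w or roi.y1 > h:
        raise ValueError(
            f"ROI {roi.blot_id}/{roi.protein}/{roi.lane_id} "
            f"({roi.x0}:{roi.x1}, {roi.y0}:{roi.y1}) exceeds image bounds {w}x{h}"
        )


def estimate_background(
    image: np.ndarray,
    roi: BandROI,
    margin: int = 3,
    exclude: Sequence[BandROI] = (),
) -> float:
    """Median intensity of the frame of ``margin`` pixels surrounding *roi*.

    Pixels of the frame that fall inside any ROI in *exclude* are ignored,
    so neighbouring bands do not contaminate the estimate.  The median makes
    the estimate robust to bright specks in the surround.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    h, w = image.shape
    bx0, by0 = roi.x0 - margin, roi.y0 - margin
    bx1, by1 = roi.x1 + margin, roi.y1 + margin
    if bx0 < 0 or by0 < 0 or bx1 > w or by1 > h:
        raise ValueError(
            f"background frame of {margin}px around ROI "
            f"{roi.blot_id}/{roi.protein}/{roi.lane_id} falls outside the image"
        )
    box = image[by0:by1, bx0:bx1]
    keep = np.ones(box.shape, dtype=bool)
    # carve out the ROI itself
    keep[margin : margin + roi.height, margin : margin + roi.width] = False
    for other in exclude:
        ox0 = max(other.x0 - bx0, 0)
        oy0 = max(other.y0 - by0, 0)
        ox1 = min(other.x1 - bx0, box.shape[1])
        oy1 = min(other.y1 - by0, box.shape[0])
        if ox1 > ox0 and oy1 > oy0:
            keep[oy0:oy1, ox0:ox1] = False
    vals = box[keep]
    if vals.size == 0:
        raise ValueError(
            f"ROI {roi.blot_id}/{roi.protein}/{roi.lane_id}: background frame empty "
            "after exclusions; ROI placement unusable"
        )
    return float(np.median(vals.astype(np.float64)))


def quantify_band(image: np.ndarray, roi: BandROI, background: float) -> float:
    """Background-corrected, width-normalized band density.

    Sum over ROI pixels of ``max(pixel - background, 0)``, divided by the
    ROI width.  Per-pixel residuals are clipped at zero so speckle noise
    below background cannot drive the density negative.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    _check_inside(image, roi)
    patch = image[roi.y0 : roi.y1, roi.x0 : roi.x1].astype(np.float64)
    residual = np.clip(patch - background, 0.0, None)
    return float(residual.sum() / roi.width)


def quantify_blot(
    image: np.ndarray,
    rois: Sequence[BandROI],
    lane_map: Mapping[str, tuple[str, str]],
    margin: int = 3,
) -> list[BandMeasurement]:
    """Quantify every ROI on a blot image.

    *lane_map* maps ``lane_id`` to ``(animal_id, group)``.  Output order is
    canonical (sorted by protein then lane), independent of input ROI order.
    """
    rois = list(rois)
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping ROIs: {a.protein}/{a.lane_id} and {b.protein}/{b.lane_id}"
                )
    unmapped = sorted({r.lane_id for r in rois} - set(lane_map))
    if unmapped:
        raise ValueError(f"lanes missing from lane_map: {', '.join(unmapped)}")
    out: list[BandMeasurement] = []
    for roi in sorted(rois, key=lambda r: (r.protein, r.lane_id)):
        others = [r for r in rois if r is not roi]
        bg = estimate_background(image, roi, margin=margin, exclude=others)
        density = quantify_band(image, roi, bg)
        animal, group = lane_map[roi.lane_id]
        out.append(
            BandMeasurement(
                blot_id=roi.blot_id,
                lane_id=roi.lane_id,
                animal_id=animal,
                group=group,
                protein=roi.protein,
                raw_density=density,
                background_level=bg,
            )
        )
    return out


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image, got shape {arr.shape}")
    return arr


def read_roi_table(path: str | Path) -> list[BandROI]:
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table {path} missing columns: {', '.join(missing)}")
    return [
        BandROI(
            blot_id=str(r.blot_id),
            protein=str(r.protein),
            lane_id=str(r.lane_id),
            x0=int(r.x0),
            y0=int(r.y0),
            width=int(r.width),
            height=int(r.height),
        )
        for r in df.itertuples()
    ]


def write_roi_table(rois: Iterable[BandROI], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in rois], columns=ROI_COLUMNS).to_csv(path, index=False)


def measurements_to_frame(measurements: Iterable[BandMeasurement]) -> pd.DataFrame:
    """Band measurements as the canonical delimited-text schema."""
    cols = ["blot_id", "lane_id", "animal_id", "group", "protein", "raw_density", "background_level"]
    return pd.DataFrame([vars(m) for m in measurements], columns=cols)
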