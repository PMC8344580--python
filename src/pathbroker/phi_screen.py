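"""Dark-region PHI screening of slide thumbnails.

A label sticker placed too close to the tissue can be captured in the
main high-resolution image, where it survives label/macro stripping.
Stickers appear as large dark areas on the digital thumbnail, so the
screen thresholds thumbnail luminance, labels connected dark
components, and flags the WSI when any component covers at least a
minimum fraction of the thumbnail.  A flagged WSI is excluded from the
compiled dataset outright — never cropped or inpainted — to virtually
eliminate the PHI-exposure risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .image_deid import WSIContainer


@dataclass(frozen=True)
class DarkRegionParams:
    """Threshold 0–255 on Rec.601 luminance; area fraction of the
    thumbnail a component must reach to qualify; 4- or 8-connectivity.

    Defaults (60/255, 0.05, 8-connectivity) are operational choices,
    exposed for tuning.
    """

    luminance_threshold: int = 60
    min_area_fraction: float = 0.05
    connectivity: int = 8

    def __post_init__(self):
        if not 0 < self.luminance_threshold < 255:
            raise ValueError("luminance_threshold must be in (0, 255)")
        if not 0 < self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class DarkRegion:
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area_fraction: float
    mean_luminance: float
    pixel_count: int


@dataclass(frozen=True)
class ScreenDecision:
    image_id: str
    flagged: bool
    regions: tuple[DarkRegion, ...]
    params: DarkRegionParams


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Integer Rec.601 luma of an 8-bit image (grayscale passed through)."""
    arr = np.asarray(rgb)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    y = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.rint(y).astype(np.uint8)


def detect_dark_regions(
    thumbnail: np.ndarray, params: DarkRegionParams = DarkRegionParams()
) -> list[DarkRegion]:
    """Connected components of pixels darker than the threshold.

    Every component is reported (qualification against
    ``min_area_fraction`` happens in :func:`screen_wsi`), ordered by
    area descending with position as tie-break.
    """
    thumbnail = np.asarray(thumbnail)
    if thumbnail.size == 0:
        raise ValueError("empty thumbnail")
    luma = luminance(thumbnail)
    mask = luma < params.luminance_threshold
    total = luma.size
    labels = measure.label(mask, connectivity=1 if params.connectivity == 4 else 2)
    regions = []
    for props in measure.regionprops(labels, intensity_image=luma):
        r0, c0, r1, c1 = props.bbox
        regions.append(
            DarkRegion(
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                area_fraction=props.area / total,
                mean_luminance=float(props.intensity_mean),
                pixel_count=int(props.area),
            )
        )
    regions.sort(key=lambda r: (-r.pixel_count, r.bbox))
    return regions


def screen_wsi(
    container: WSIContainer,
    params: DarkRegionParams = DarkRegionParams(),
    image_id: str = "",
) -> ScreenDecision:
    """Screen one slide; flagged iff any region reaches the minimum
    area fraction (``>=`` at the boundary).  Pure decision — the
    container is never modified; parameters are recorded for audit.
    """
    thumb = container.thumbnail_pixels()
    regions = detect_dark_regions(thumb, params)
    flagged = any(r.area_fraction >= params.min_area_fraction for r in regions)
    return ScreenDecision(
        image_id=image_id or container.path.stem,
        flagged=flagged,
        regions=tuple(regions),
        params=params,
    )
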