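"""DAPI-guided nucleus segmentation.

The DAPI channel defines the per-cell regions used to crop the gamma-H2AX
signal channel: background is subtracted, nuclei are thresholded (Otsu by
default) and labeled as connected components, touching nuclei are optionally
split by a distance-transform watershed, and regions are filtered by area and
border contact.  Nucleus masks stand in for cells throughout — gamma-H2AX is
a nuclear mark, so the nucleus is the biologically relevant crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.filters.rank import median as rank_median
from skimage.morphology import disk
from skimage.restoration import rolling_ball
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "LabelMap",
    "SegmentationParams",
    "subtract_background",
    "segment_nuclei",
    "filter_labels",
]


@dataclass(frozen=True)
class LabelMap:
    """Integer label image: 0 is background, nuclei are 1..n_labels."""

    labels: np.ndarray
    n_labels: int

    def __post_init__(self) -> None:
        lbl = self.labels
        if lbl.ndim != 2:
            raise ValueError("label image must be 2-D")
        present = np.unique(lbl)
        present = present[present > 0]
        expected = np.arange(1, self.n_labels + 1)
        if not np.array_equal(present, expected):
            raise ValueError(
                f"labels must be consecutive 1..{self.n_labels}, got {present}"
            )

    @staticmethod
    def from_labels(labels: np.ndarray) -> "LabelMap":
        labels = np.asarray(labels)
        n = int(labels.max()) if labels.size else 0
        return LabelMap(labels=labels, n_labels=n)


@dataclass(frozen=True)
class SegmentationParams:
    background_method: str = "median"  # rolling_ball | median | none
    background_radius: int = 25
    dapi_threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold: float | None = None
    min_area: int = 40
    max_area: int | None = None
    exclude_border: bool = True
    split_touching: bool = False
    split_min_distance: int = 5
    connectivity: int = 8  # 4 or 8

    def __post_init__(self) -> None:
        if self.background_method not in ("rolling_ball", "median", "none"):
            raise ValueError(f"unknown background method {self.background_method!r}")
        if self.background_method != "none" and self.background_radius < 1:
            raise ValueError("background_radius must be >= 1")
        if self.dapi_threshold_method not in ("otsu", "fixed"):
            raise ValueError(
                f"unknown threshold method {self.dapi_threshold_method!r}"
            )
        if self.dapi_threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed thresholding requires fixed_threshold")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def ndi_structure(self) -> np.ndarray:
        return ndi.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


def subtract_background(
    image: np.ndarray, method: str = "median", radius: int = 25
) -> np.ndarray:
    """Estimate and remove slowly varying background, clipping at zero.

    ``median`` subtracts a disk-footprint median filter (exact on integer
    images via a sliding-histogram rank filter, so a constant background is
    removed without residue); ``rolling_ball`` subtracts the morphological
    rolling-ball background; ``none`` returns the input unchanged.  Output is
    float, same shape, non-negative.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if method == "none":
        return img.astype(float, copy=True)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(img.shape):
        raise ValueError(
            f"background radius {radius} exceeds image extent {img.shape}"
        )
    if method == "median":
        if img.dtype in (np.uint8, np.uint16):
            bg = rank_median(img, footprint=disk(radius)).astype(float)
        else:
            bg = ndi.median_filter(img.astype(float), footprint=disk(radius))
    elif method == "rolling_ball":
        bg = rolling_ball(img.astype(float), radius=radius)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.clip(img.astype(float) - bg, 0.0, None)


def _split_touching(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Watershed on the distance transform, seeded at distance maxima."""
    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance,
        min_distance=params.split_min_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(
        ndi.binary_dilation(markers > 0, structure=params.ndi_structure),
        structure=params.ndi_structure,
    )
    return watershed(-distance, markers, mask=mask)


def segment_nuclei(dapi: np.ndarray, params: SegmentationParams | None = None) -> LabelMap:
    """Segment nuclei from the DAPI channel.

    Chain: background subtraction -> intensity threshold -> connected
    components -> optional watershed split -> area/border filter.  An image
    with no foreground (including an all-constant image, where Otsu is
    undefined) yields an empty LabelMap rather than an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(dapi)
    if img.ndim != 2:
        raise ValueError("DAPI image must be 2-D, single channel")
    corrected = subtract_background(
        img, params.background_method, params.background_radius
    )
    if params.dapi_threshold_method == "fixed":
        thr = float(params.fixed_threshold)
    else:
        if np.ptp(corrected) == 0:
            return LabelMap(np.zeros(img.shape, dtype=np.int32), 0)
        thr = float(threshold_otsu(corrected))
    mask = corrected > thr
    if not mask.any():
        return LabelMap(np.zeros(img.shape, dtype=np.int32), 0)
    if params.split_touching:
        labels = _split_touching(mask, params)
    else:
        labels, _ = ndi.label(mask, structure=params.ndi_structure)
    lm = LabelMap.from_labels(labels.astype(np.int32))
    return filter_labels(lm, params.min_area, params.max_area, params.exclude_border)


def filter_labels(
    label_map: LabelMap,
    min_area: int = 1,
    max_area: int | None = None,
    exclude_border: bool = False,
) -> LabelMap:
    """Drop labels by area or border contact; survivors are renumbered 1..k."""
    lbl = label_map.labels
    if label_map.n_labels == 0:
        return label_map
    areas = np.bincount(lbl.ravel(), minlength=label_map.n_labels + 1)
    keep = np.ones(label_map.n_labels + 1, dtype=bool)
    keep[0] = False
    keep[1:] &= areas[1:] >= min_area
    if max_area is not None:
        keep[1:] &= areas[1:] <= max_area
    if exclude_border:
        border = np.concatenate(
            [lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]]
        )
        keep[np.unique(border[border > 0])] = False
    filtered = np.where(keep[lbl], lbl, 0)
    relabeled, _, _ = relabel_sequential(filtered)
    return LabelMap.from_labels(relabeled.astype(np.int32))
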