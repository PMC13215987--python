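"""From a binary adipose mask to anatomical compartments.

The adipose mask produced by segmentation is decomposed into 8-connected
regions.  Arm fat is removed by intersecting with an abdominal mask, and
the remaining adipose tissue is split into subcutaneous (SAT) and visceral
(VAT) compartments by a centroid-distance rule: of the two largest
regions, the one whose centroid lies farther from the image center is the
peripheral SAT ring; the nearer one — and every smaller fragment — is VAT,
the fragmented central compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk

from .phantom import CompartmentMasks

DISTANCE_TIE_TOL = 1e-9


class DelineationWarning(UserWarning):
    """Non-fatal anomaly during VAT/SAT delineation (possible SAT-VAT bridge)."""


@dataclass(frozen=True)
class RegionProps:
    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    centroid_center_distance_px: float


def image_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Geometric center in pixel coordinates: ((rows-1)/2, (cols-1)/2)."""
    return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


def label_regions(mask: np.ndarray) -> np.ndarray:
    """Label 8-connected components; 0 = background, labels contiguous 1..R."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    return sk_label(mask, connectivity=2)


def region_props(
    labeled: np.ndarray, center: tuple[float, float] | None = None
) -> list[RegionProps]:
    """Per-region area, centroid and centroid-to-center distance.

    Sorted by area descending (ties by label ascending).
    """
    if center is None:
        center = image_center(labeled.shape)
    props = []
    for rp in regionprops(labeled):
        cr, cc = rp.centroid
        dist = float(np.hypot(cr - center[0], cc - center[1]))
        props.append(
            RegionProps(
                label=int(rp.label),
                area_px=int(rp.area),
                centroid=(float(cr), float(cc)),
                centroid_center_distance_px=dist,
            )
        )
    return sorted(props, key=lambda p: (-p.area_px, p.label))


def apply_abdominal_mask(mask: np.ndarray, abdominal: np.ndarray) -> np.ndarray:
    """Suppress everything outside the abdominal region (pointwise AND)."""
    mask = np.asarray(mask)
    abdominal = np.asarray(abdominal)
    if mask.shape != abdominal.shape:
        raise ValueError(
            f"mask shape {mask.shape} != abdominal mask shape {abdominal.shape}"
        )
    return ((mask > 0) & (abdominal > 0)).astype(np.uint8)


def build_abdominal_mask(
    body_image: np.ndarray, closing_radius_px: int = 10
) -> np.ndarray:
    """Construct an arm-exclusion mask from the raw slice.

    Foreground is thresholded with Otsu on the raw image, closed with a
    disk, and the single 8-connected component containing (or nearest to)
    the image center is kept and hole-filled.  Arms, being laterally
    disconnected from the trunk, fall outside this component.  A manually
    drawn mask can always be supplied instead.
    """
    img = np.asarray(body_image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    fg = img > threshold_otsu(img)
    fg = closing(fg, footprint=disk(closing_radius_px))
    # Fill holes before picking the central component: on fat-bright
    # slices the threshold may keep only the subcutaneous ring, and hole
    # filling turns that ring into the solid trunk so the image center
    # falls inside it.
    fg = binary_fill_holes(fg)
    labeled = sk_label(fg, connectivity=2)
    if labeled.max() == 0:
        raise ValueError(
            "no foreground component found; supply an abdominal mask manually"
        )
    cr, cc = image_center(img.shape)
    center_label = labeled[int(round(cr)), int(round(cc))]
    if center_label == 0:
        # fall back to the component whose pixels come nearest the center
        rows, cols = np.nonzero(labeled)
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        center_label = labeled[rows[np.argmin(d2)], cols[np.argmin(d2)]]
    body = labeled == center_label
    return binary_fill_holes(body).astype(np.uint8)


def delineate_vat_sat(
    adipose_mask: np.ndarray,
    center: tuple[float, float] | None = None,
    k_largest: int = 2,
) -> CompartmentMasks:
    """Split an (arm-free) adipose mask into SAT and VAT.

    Among the ``k_largest`` (default two) largest 8-connected regions the
    one with the larger centroid-to-center distance becomes SAT and the
    rest VAT; every smaller region is VAT.  A single region is taken as SAT
    with a warning (suggests SAT-VAT bridging); an exact distance tie is
    broken by area, also with a warning.
    """
    adipose_mask = np.asarray(adipose_mask)
    if center is None:
        center = image_center(adipose_mask.shape)
    labeled = label_regions(adipose_mask)
    props = region_props(labeled, center)
    if not props:
        raise ValueError("adipose mask is empty; nothing to delineate")
    sat = np.zeros(adipose_mask.shape, dtype=np.uint8)
    vat = np.zeros(adipose_mask.shape, dtype=np.uint8)
    if len(props) == 1:
        warnings.warn(
            "only one adipose region found; labeling it SAT with empty VAT "
            "(possible SAT-VAT bridging)",
            DelineationWarning,
        )
        sat[labeled == props[0].label] = 1
        return CompartmentMasks(sat=sat, vat=vat)

    top = props[: max(2, k_largest)]
    distances = [p.centroid_center_distance_px for p in top]
    best = int(np.argmax(distances))
    ties = [
        i
        for i, d in enumerate(distances)
        if i != best and abs(d - distances[best]) <= DISTANCE_TIE_TOL
    ]
    if ties:
        warnings.warn(
            "centroid-center distance tie among largest regions; choosing "
            "the larger area as SAT",
            DelineationWarning,
        )
        cand = [best] + ties
        best = cand[int(np.argmax([top[i].area_px for i in cand]))]
    sat_label = top[best].label
    sat[labeled == sat_label] = 1
    vat[(labeled > 0) & (labeled != sat_label)] = 1
    return CompartmentMasks(sat=sat, vat=vat)
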