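"""Oocyte mitochondrial distribution: relative peripheral intensity.

During bovine oocyte maturation, aerobically active mitochondria relocate
from a cortical ring (immature, germinal-vesicle stage) to a diffuse central
pattern (metaphase II).  The metric implemented here is the ratio of the mean
per-pixel Mitotracker fluorescence in the cortex — the outer 20% of the
oocyte diameter, i.e. the annulus between 80% and 100% of the radius — to
that of the center (the inner 80% of the diameter), measured on the
equatorial optical section (the z-plane with the largest cross-section).
A ratio near 1 indicates a diffuse distribution, values well above 1 a
peripheral ring.  Per-pixel means normalise away the area difference between
the two compartments, so the compartment boundary convention does not bias
the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ParameterError, SegmentationError
from .scene import MultiChannelScene


@dataclass
class SegmentedOocyte:
    """Binary oocyte mask plus derived geometry for one optical plane."""

    mask: np.ndarray
    center_xy: tuple[float, float]  # (x, y), subpixel
    diameter_px: float  # equivalent circular diameter 2*sqrt(area/pi)
    plane_index: int = 0

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class MitoProfile:
    """Cortex/center per-pixel mean intensities and their ratio (AU)."""

    center_mean: float
    cortex_mean: float
    relative_peripheral_intensity: float  # nan when undefined (center_mean 0)
    center_fraction: float = 0.8

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.relative_peripheral_intensity)


def segment_oocyte(plane: np.ndarray, plane_index: int = 0) -> SegmentedOocyte:
    """Segment the oocyte as the largest Otsu-foreground component.

    Holes are filled; small bright debris is excluded by the
    largest-component rule.  Raises :class:`SegmentationError` when the
    foreground covers less than 1% of the frame (no oocyte in view).
    """
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ParameterError("empty plane")
    if np.ptp(plane) == 0:
        raise SegmentationError("no oocyte detected (constant image)")
    thr = threshold_otsu(plane)
    fg = plane > thr
    if fg.sum() < 0.01 * plane.size:
        raise SegmentationError("no oocyte detected (foreground < 1% of frame)")
    labels = label(fg)
    regions = regionprops(labels)
    biggest = max(regions, key=lambda r: r.area)
    mask = ndi.binary_fill_holes(labels == biggest.label)
    area = float(mask.sum())
    cy, cx = ndi.center_of_mass(mask)
    diameter = 2.0 * np.sqrt(area / np.pi)
    return SegmentedOocyte(
        mask=mask, center_xy=(float(cx), float(cy)), diameter_px=diameter,
        plane_index=plane_index,
    )


def select_equator(scene: MultiChannelScene, role: str = "mito") -> int:
    """Index of the z-plane with the largest segmented oocyte cross-section.

    Ties are broken toward the middle of the stack.  Raises
    :class:`SegmentationError` if no plane segments successfully.
    """
    stack = scene.stack(role)
    n = stack.shape[0]
    mid = (n - 1) / 2.0
    best: tuple[float, float, int] | None = None
    any_ok = False
    for i in range(n):
        try:
            seg = segment_oocyte(stack[i], plane_index=i)
        except SegmentationError:
            continue
        any_ok = True
        key = (-seg.area_px, abs(i - mid), i)
        if best is None or key < best:
            best = key
    if not any_ok or best is None:
        raise SegmentationError("no z-plane contains a segmentable oocyte")
    return int(best[2])


def relative_peripheral_intensity(
    plane: np.ndarray,
    oocyte: SegmentedOocyte,
    center_fraction: float = 0.8,
) -> MitoProfile:
    """Cortex vs center per-pixel mean ratio on one optical section.

    ``center_fraction`` is the fraction of the diameter assigned to the
    center compartment (default 0.8, i.e. a 10% peripheral band on each
    side).  When the center mean is zero the ratio is reported as NaN
    (undefined), never infinity.
    """
    if not 0 < center_fraction < 1:
        raise ParameterError("center_fraction must be in (0, 1)")
    plane = np.asarray(plane, dtype=float)
    if plane.shape != oocyte.mask.shape:
        raise ParameterError("plane and mask shapes differ")

    cx, cy = oocyte.center_xy
    yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
    dist = np.hypot(yy - cy, xx - cx)
    r_center = center_fraction * oocyte.diameter_px / 2.0
    center_region = oocyte.mask & (dist <= r_center)
    cortex_region = oocyte.mask & ~center_region

    if not center_region.any() or not cortex_region.any():
        raise SegmentationError("degenerate compartments (empty center or cortex)")

    center_mean = float(plane[center_region].mean())
    cortex_mean = float(plane[cortex_region].mean())
    ratio = cortex_mean / center_mean if center_mean > 0 else float("nan")
    return MitoProfile(
        center_mean=center_mean,
        cortex_mean=cortex_mean,
        relative_peripheral_intensity=ratio,
        center_fraction=center_fraction,
    )


def profile_scene(
    scene: MultiChannelScene,
    center_fraction: float = 0.8,
    aggregate_planes: bool = False,
) -> tuple[MitoProfile, SegmentedOocyte]:
    """Full per-oocyte measurement: equator selection + compartment ratio.

    With ``aggregate_planes`` the ratio is averaged over every segmentable
    z-plane instead of using the single equatorial section.
    """
    if aggregate_planes and scene.n_z > 1:
        stack = scene.stack("mito")
        profiles = []
        seg_eq = None
        eq = select_equator(scene)
        for i in range(stack.shape[0]):
            try:
                seg = segment_oocyte(stack[i], plane_index=i)
            except SegmentationError:
                continue
            profiles.append(relative_peripheral_intensity(stack[i], seg, center_fraction))
            if i == eq:
                seg_eq = seg
        ratios = [p.relative_peripheral_intensity for p in profiles]
        mean_profile = MitoProfile(
            center_mean=float(np.mean([p.center_mean for p in profiles])),
            cortex_mean=float(np.mean([p.cortex_mean for p in profiles])),
            relative_peripheral_intensity=float(np.nanmean(ratios)),
            center_fraction=center_fraction,
        )
        assert seg_eq is not None
        return mean_profile, seg_eq

    eq = select_equator(scene)
    plane = scene.plane("mito", eq)
    seg = segment_oocyte(plane, plane_index=eq)
    return relative_peripheral_intensity(plane, seg, center_fraction), seg
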