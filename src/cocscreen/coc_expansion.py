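"""Cumulus–oocyte complex expansion: projected area and fold-increase.

During the final stages of in-vitro maturation the cumulus layer secretes a
hyaluronic-acid-rich matrix and the projected area of the COC grows severalfold
(typically ~2.8–3.8x in the bovine assay).  The endpoint is the ratio of the
projected surface area (in pixels) of each COC after vs before maturation.
Only the 2-D projection is measured; volume changes and the oocyte-vs-cumulus
contribution are not resolved.  The fold is reported at full precision; the
reporting layer rounds to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import PairingError, ParameterError, SegmentationError


@dataclass
class ExpansionRecord:
    coc_id: str
    area_before_px: int
    area_after_px: int

    @property
    def fold_increase(self) -> float:
        return fold_increase(self.area_before_px, self.area_after_px)


def segment_coc_area(plane: np.ndarray) -> tuple[np.ndarray, int]:
    """Projected COC area: largest Otsu component with holes filled.

    Hole filling includes the darker oocyte shadow often visible inside the
    cumulus mass.  Raises :class:`SegmentationError` when no foreground is
    found.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ParameterError("empty plane")
    if np.ptp(plane) == 0:
        raise SegmentationError("no COC detected (constant image)")
    thr = threshold_otsu(plane)
    fg = plane > thr
    if not fg.any():
        raise SegmentationError("no COC detected")
    labels = label(fg)
    biggest = max(regionprops(labels), key=lambda r: r.area)
    mask = ndi.binary_fill_holes(labels == biggest.label)
    return mask, int(mask.sum())


def fold_increase(area_before_px: float, area_after_px: float) -> float:
    """Exact after/before area quotient (full precision)."""
    if area_before_px <= 0 or area_after_px <= 0:
        raise ParameterError("areas must be positive")
    return float(area_after_px) / float(area_before_px)


def pair_and_tabulate(
    before_measurements: Mapping[str, int],
    after_measurements: Mapping[str, int],
    id_map: Mapping[str, str] | None = None,
) -> list[ExpansionRecord]:
    """Match before/after areas one-to-one into :class:`ExpansionRecord`s.

    ``id_map`` maps before-ids to after-ids (identity by default).  Unmatched
    or duplicate ids raise :class:`PairingError` naming the offenders; nothing
    is silently dropped.
    """
    before = dict(before_measurements)
    after = dict(after_measurements)
    if len(before) != len(before_measurements) or len(after) != len(after_measurements):
        raise PairingError("duplicate ids in measurements")
    if id_map is None:
        id_map = {k: k for k in before}
    if len(set(id_map.values())) != len(id_map):
        raise PairingError("id_map maps multiple before-ids to one after-id")

    unmatched = sorted(set(before) - set(id_map)) + sorted(
        set(id_map.values()) - set(after)
    ) + sorted(set(after) - set(id_map.values())) + sorted(set(id_map) - set(before))
    if unmatched:
        raise PairingError(f"unmatched ids: {unmatched}")

    return [
        ExpansionRecord(
            coc_id=bid,
            area_before_px=int(before[bid]),
            area_after_px=int(after[id_map[bid]]),
        )
        for bid in sorted(before)
    ]


def records_to_frame(records: Iterable[ExpansionRecord]) -> pd.DataFrame:
    """Tabulate records with both full-precision and 1-decimal folds."""
    rows = [
        {
            "coc_id": r.coc_id,
            "area_before_px": r.area_before_px,
            "area_after_px": r.area_after_px,
            "fold_increase": r.fold_increase,
            "fold_increase_1dp": float(np.round(r.fold_increase, 1)),
        }
        for r in records
    ]
    return pd.DataFrame(rows)
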