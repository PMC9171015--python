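"""Seeded synthetic fluorescence scenes and outcome tables with known truth.

Every analysis stage of the pipeline has a generator here that produces its
input together with a :class:`SceneTruth` record, so recovery of the ground
truth can be tested end to end without any external data:

* :func:`make_oocyte_scene` — a Mitotracker-stained oocyte as a z-stack of
  sphere cross-sections whose cortex/center per-pixel intensity ratio is set
  exactly (before noise).
* :func:`make_expansion_pair` — a cumulus–oocyte complex photographed before
  and after in-vitro maturation, as two bright blobs whose projected pixel
  areas differ by a prescribed fold.
* :func:`make_coc_nucleus_scene` — a field of Hoechst-positive cumulus-cell
  nuclei with apoptotic (TUNEL), necrotic (EthD-1) and secondary
  (double-positive) subpopulations.
* :func:`simulate_experiment_counts` / :func:`simulate_steroid_table` —
  multinomial outcome tables and truncated-normal steroid concentrations.

All randomness flows from a single root seed through
:class:`numpy.random.SeedSequence` substreams, so identical arguments give
bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError
from .scene import MultiChannelScene

NUCLEUS_CLASSES = ("healthy", "apoptotic", "necrotic_only", "secondary")

#: Steroids detectable above LOD in conditioned maturation media.
STEROID_PANEL = (
    "pregnenolone",
    "progesterone",
    "testosterone",
    "estrone",
    "17b-estradiol",
)

#: Default per-group means (ng/ml) for the two steroids the showcase compound
#: (DES at 1e-5 M during IVM) shifts: pregnenolone 2.79 -> 7.30 and
#: progesterone 6.40 -> 11.20 versus vehicle-treated cultures.
DEFAULT_STEROID_MEANS = {
    ("pregnenolone", "vehicle"): 2.79,
    ("pregnenolone", "DES 1e-5 M"): 7.30,
    ("progesterone", "vehicle"): 6.40,
    ("progesterone", "DES 1e-5 M"): 11.20,
}
DEFAULT_STEROID_SDS = {
    ("pregnenolone", "vehicle"): 0.28,
    ("pregnenolone", "DES 1e-5 M"): 0.89,
    ("progesterone", "vehicle"): 0.47,
    ("progesterone", "DES 1e-5 M"): 0.86,
}


@dataclass
class SceneTruth:
    """Ground truth attached to a generated scene."""

    kind: str  # oocyte | expansion_pair | nucleus_field
    seed: int
    true_ratio: float | None = None
    true_area_px: tuple[int, int] | None = None
    nucleus_truth: list[tuple[tuple[float, float], str]] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in NUCLEUS_CLASSES}
        for _, cls in self.nucleus_truth:
            counts[cls] += 1
        return counts


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=stream))


# ---------------------------------------------------------------------------
# oocyte scenes
# ---------------------------------------------------------------------------

def make_oocyte_scene(
    radius_px: int = 100,
    true_ratio: float = 1.4,
    noise_sd: float = 0.0,
    n_z: int = 1,
    seed: int = 0,
    center_fraction: float = 0.8,
    base_intensity: float = 100.0,
) -> tuple[MultiChannelScene, SceneTruth]:
    """Render a Mitotracker-stained oocyte with a known cortex/center ratio.

    The oocyte is a sphere of radius ``radius_px``; each z-plane is the
    corresponding circular cross-section, the middle plane being the equator
    (largest cross-section).  Within each plane the inner disc out to
    ``center_fraction`` of the local radius has per-pixel intensity
    ``base_intensity`` and the outer annulus ``base_intensity * true_ratio``,
    so the relative peripheral intensity equals ``true_ratio`` exactly before
    noise.  ``true_ratio = 1.4`` is the vehicle-group default of the assay.
    """
    if radius_px < 20:
        raise ParameterError("radius_px must be >= 20 to hold both compartments")
    if true_ratio <= 0:
        raise ParameterError("true_ratio must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    if n_z < 1:
        raise ParameterError("n_z must be >= 1")
    if not 0 < center_fraction < 1:
        raise ParameterError("center_fraction must be in (0, 1)")

    rng = _rng(seed, 0)
    margin = max(8, radius_px // 5)
    size = 2 * radius_px + 2 * margin
    cy = cx = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - cy, xx - cx)

    mid = (n_z - 1) / 2.0
    planes = np.zeros((n_z, size, size), dtype=float)
    for i in range(n_z):
        # normalised axial offset; < 1 everywhere so every plane is nonempty,
        # strictly maximal at the stack middle
        f = (i - mid) / (mid + 1.0) if n_z > 1 else 0.0
        r_plane = radius_px * np.sqrt(max(1.0 - f * f, 0.0))
        inside = dist <= r_plane
        center = dist <= center_fraction * r_plane
        plane = np.zeros((size, size), dtype=float)
        plane[inside] = base_intensity * true_ratio
        plane[center] = base_intensity
        planes[i] = plane

    if noise_sd > 0:
        planes = np.clip(planes + rng.normal(0.0, noise_sd, planes.shape), 0.0, None)

    pixels = planes[:, None, :, :]  # (z, c, y, x), one mito channel
    scene = MultiChannelScene(pixels=pixels, channel_roles={0: "mito"}, z_step_um=2.0)
    truth = SceneTruth(kind="oocyte", seed=seed, true_ratio=float(true_ratio))
    return scene, truth


# ---------------------------------------------------------------------------
# expansion pairs
# ---------------------------------------------------------------------------

def _raster_blob(
    target_area: float,
    irregularity: float,
    frame: int,
    rng: np.random.Generator,
    fg: float,
    bg: float,
) -> tuple[np.ndarray, int]:
    """Rasterize a star-convex blob of (approximately) ``target_area`` pixels."""
    cy = cx = (frame - 1) / 2.0
    yy, xx = np.mgrid[0:frame, 0:frame]
    theta = np.arctan2(yy - cy, xx - cx)
    dist = np.hypot(yy - cy, xx - cx)

    # low-order radial harmonics; amplitudes bounded so the boundary stays
    # positive and the blob star-convex
    n_harm = 4
    amps = irregularity * 0.25 * rng.uniform(0.3, 1.0, n_harm) / np.arange(1, n_harm + 1)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    shape_fn = 1.0 + sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases))
    )

    r0 = np.sqrt(target_area / np.pi)
    area = 0
    mask = np.zeros((frame, frame), dtype=bool)
    for _ in range(6):
        mask = dist <= r0 * shape_fn
        area = int(mask.sum())
        if area == 0:
            r0 *= 1.5
            continue
        if abs(area - target_area) / target_area < 0.003:
            break
        r0 *= np.sqrt(target_area / area)
    img = np.full((frame, frame), bg, dtype=float)
    img[mask] = fg
    return img, area


def make_expansion_pair(
    area_before_px: int = 13231,
    fold: float = 2.877,
    irregularity: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.0,
    frame: int | None = None,
) -> tuple[tuple[MultiChannelScene, MultiChannelScene], SceneTruth]:
    """Render a COC before/after maturation as two bright blobs.

    The projected foreground areas are ``area_before_px`` and
    ``round(fold * area_before_px)`` within 1% after rasterization.  The
    assay-typical defaults reproduce the worked example of the expansion
    endpoint (13,231 px expanding ~2.9-fold to ~38,061 px).
    """
    if area_before_px <= 0:
        raise ParameterError("area_before_px must be positive")
    if fold <= 0:
        raise ParameterError("fold must be positive")
    if not 0 <= irregularity <= 1:
        raise ParameterError("irregularity must be in [0, 1]")

    area_after = int(round(fold * area_before_px))
    r_max = np.sqrt(max(area_before_px, area_after) / np.pi) * (1.0 + 0.3 * irregularity)
    needed = int(np.ceil(2 * r_max + 16))
    if frame is None:
        frame = needed
    elif frame < needed:
        raise ParameterError(
            f"requested areas need a frame of >= {needed} px, got {frame}"
        )

    scenes = []
    areas = []
    for i, target in enumerate((area_before_px, area_after)):
        rng = _rng(seed, 1, i)
        img, area = _raster_blob(target, irregularity, frame, rng, fg=180.0, bg=20.0)
        if abs(area - target) / target > 0.01:
            raise ParameterError("could not rasterize blob within 1% of requested area")
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
        scenes.append(
            MultiChannelScene(pixels=img[None], channel_roles={0: "brightfield"})
        )
        areas.append(area)

    truth = SceneTruth(kind="expansion_pair", seed=seed, true_area_px=(areas[0], areas[1]))
    return (scenes[0], scenes[1]), truth


# ---------------------------------------------------------------------------
# nucleus fields
# ---------------------------------------------------------------------------

def _place_spots(
    n: int,
    frame: tuple[int, int],
    margin: float,
    min_sep: float,
    rng: np.random.Generator,
    max_tries_per_spot: int = 400,
) -> np.ndarray:
    """Uniform random centers honoring a minimum pairwise separation."""
    h, w = frame
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        raise PlacementError("frame too small for spot margin")
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_spot * max(n, 1)
    while len(pts) < n:
        if tries >= budget:
            raise PlacementError(
                f"placed only {len(pts)}/{n} spots at min separation {min_sep}"
            )
        tries += 1
        y = rng.uniform(margin, h - 1 - margin)
        x = rng.uniform(margin, w - 1 - margin)
        if min_sep > 0 and pts:
            d = np.hypot(
                np.array([p[0] for p in pts]) - y, np.array([p[1] for p in pts]) - x
            )
            if d.min() < min_sep:
                continue
        pts.append((y, x))
    return np.array(pts).reshape(n, 2)


def _render_spots(
    frame: tuple[int, int],
    centers: np.ndarray,
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of 2-D Gaussian spots truncated at 3 sigma."""
    img = np.zeros(frame, dtype=float)
    r = int(np.ceil(3 * sigma))
    h, w = frame
    for cy, cx in centers:
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        y0c, y1c = max(y0, 0), min(y1, h)
        x0c, x1c = max(x0, 0), min(x1, w)
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        g = amplitude * np.exp(-d2 / (2 * sigma**2))
        g[d2 > (3 * sigma) ** 2] = 0.0
        img[y0c:y1c, x0c:x1c] += g
    return img


def make_coc_nucleus_scene(
    n_total: int = 250,
    n_tunel_only: int = 0,
    n_ethd1_only: int = 0,
    n_double: int = 0,
    spot_sigma_px: float = 3.0,
    min_sep_px: float = 14.0,
    bg_gradient: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame: tuple[int, int] = (512, 512),
    amplitude: float = 150.0,
    bg_level: float = 10.0,
) -> tuple[MultiChannelScene, SceneTruth]:
    """Render a three-channel cumulus nucleus field with known classes.

    The Hoechst channel holds ``n_total`` Gaussian-spot nuclei; the TUNEL
    channel lights the apoptotic (TUNEL-only) and secondary (double-positive)
    nuclei; the EthD-1 channel lights the necrotic-only and secondary nuclei.
    ``min_sep_px = 0`` produces touching nuclei as a watershed stress case.
    The default density (~250 nuclei in 512 px) matches a confocal
    cross-section of a matured COC.
    """
    if n_total < 0 or min(n_tunel_only, n_ethd1_only, n_double) < 0:
        raise ParameterError("counts must be nonnegative")
    if n_tunel_only + n_ethd1_only + n_double > n_total:
        raise ParameterError("class counts exceed n_total")
    if spot_sigma_px <= 0:
        raise ParameterError("spot_sigma_px must be positive")

    rng = _rng(seed, 2)
    margin = 3 * spot_sigma_px + 2
    centers = _place_spots(n_total, frame, margin, min_sep_px, rng)

    classes = np.array(["healthy"] * n_total, dtype=object)
    order = rng.permutation(n_total)
    k = 0
    classes[order[k : k + n_tunel_only]] = "apoptotic"
    k += n_tunel_only
    classes[order[k : k + n_ethd1_only]] = "necrotic_only"
    k += n_ethd1_only
    classes[order[k : k + n_double]] = "secondary"

    hoechst = _render_spots(frame, centers, spot_sigma_px, amplitude)
    tunel_sel = np.isin(classes, ("apoptotic", "secondary"))
    ethd1_sel = np.isin(classes, ("necrotic_only", "secondary"))
    tunel = _render_spots(frame, centers[tunel_sel], spot_sigma_px, amplitude)
    ethd1 = _render_spots(frame, centers[ethd1_sel], spot_sigma_px, amplitude)

    chans = np.stack([hoechst, tunel, ethd1])
    chans += bg_level
    if bg_gradient:
        ramp = 15.0 * np.linspace(0, 1, frame[1])[None, :] * np.ones((frame[0], 1))
        chans += ramp[None]
    if noise_sd > 0:
        chans = np.clip(chans + rng.normal(0.0, noise_sd, chans.shape), 0.0, None)

    scene = MultiChannelScene(
        pixels=chans,
        channel_roles={0: "hoechst", 1: "tunel", 2: "ethd1"},
    )
    truth = SceneTruth(
        kind="nucleus_field",
        seed=seed,
        nucleus_truth=[((float(y), float(x)), str(c)) for (y, x), c in zip(centers, classes)],
    )
    return scene, truth


# ---------------------------------------------------------------------------
# outcome tables
# ---------------------------------------------------------------------------

def simulate_experiment_counts(
    category_probs: dict[str, np.ndarray | list[float]],
    n_per_group: dict[str, int] | int,
    categories: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One multinomial draw per experimental group.

    Returns a group x category count matrix (DataFrame, groups as rows).
    """
    groups = list(category_probs)
    if not groups:
        raise ParameterError("need at least one group")
    n_cat = len(next(iter(category_probs.values())))
    if categories is None:
        categories = [f"cat{i}" for i in range(n_cat)]
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in groups}

    rng = _rng(seed, 3)
    rows = {}
    for g in groups:
        p = np.asarray(category_probs[g], dtype=float)
        if p.min() < 0:
            raise ParameterError(f"negative probability for group {g!r}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError(f"probabilities for group {g!r} do not sum to 1")
        if len(p) != len(categories):
            raise ParameterError("probability vector length mismatch")
        rows[g] = rng.multinomial(int(n_per_group[g]), p)
    return pd.DataFrame.from_dict(rows, orient="index", columns=categories)


def simulate_steroid_table(
    group_means: dict[tuple[str, str], float] | None = None,
    group_sds: dict[tuple[str, str], float] | None = None,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Truncated-at-zero normal steroid concentrations per (analyte, group).

    Defaults reproduce the assay's vehicle vs high-DES pregnenolone and
    progesterone levels.  Returns a long table with columns
    ``group, replicate, analyte, concentration_ng_ml``.
    """
    if group_means is None:
        group_means = dict(DEFAULT_STEROID_MEANS)
    if group_sds is None:
        group_sds = {k: DEFAULT_STEROID_SDS.get(k, 0.0) for k in group_means}
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")

    rng = _rng(seed, 4)
    records = []
    for (analyte, group), mean in group_means.items():
        if analyte not in STEROID_PANEL:
            raise ParameterError(f"unknown analyte {analyte!r}")
        sd = float(group_sds.get((analyte, group), 0.0))
        if sd < 0:
            raise ParameterError("sds must be nonnegative")
        if mean < 0:
            raise ParameterError("means must be nonnegative")
        for rep in range(1, n_reps + 1):
            if sd == 0:
                value = mean
            else:
                # truncated-at-zero normal by rejection; concentrations cannot
                # be negative
                value = -1.0
                while value < 0:
                    value = rng.normal(mean, sd)
            records.append(
                {
                    "group": group,
                    "replicate": rep,
                    "analyte": analyte,
                    "concentration_ng_ml": float(value),
                }
            )
    return pd.DataFrame.from_records(records)
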