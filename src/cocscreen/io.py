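"""File formats: multi-page TIFF scenes with JSON sidecars, CSV tables.

Scenes are written as multi-page TIFF (pages = flattened z x channel, 16-bit
unsigned) with a ``<name>.json`` sidecar recording the array shape, the
channel-role map and the pixel calibration.  Raw intensity values are
preserved: no normalisation is applied on read or write, so 8- and 16-bit
inputs yield identical downstream ratios.

CSV schemas (UTF-8, header row):

* counts — ``group,category,count`` (long form);
* values — ``group,replicate,value`` (long form);
* nucleus tables / cytometry / expansion records as written by the pipeline.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError, TableFormatError
from .scene import VALID_ROLES, MultiChannelScene


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_scene(scene: MultiChannelScene, path: str | Path) -> Path:
    """Write a scene as multi-page 16-bit TIFF plus a JSON channel-map sidecar."""
    path = Path(path)
    pixels = scene.pixels
    if pixels.max() > np.iinfo(np.uint16).max:
        raise ParameterError("intensities exceed the 16-bit range")
    flat = pixels.reshape((-1,) + scene.frame_shape)
    tifffile.imwrite(path, np.round(flat).astype(np.uint16), photometric="minisblack")
    meta = {
        "scene_id": scene.scene_id,
        "shape": list(pixels.shape),
        "has_z": scene.has_z,
        "channel_roles": {str(k): v for k, v in scene.channel_roles.items()},
        "pixel_size_um": scene.pixel_size_um,
        "z_step_um": scene.z_step_um,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_scene(path: str | Path, channel_roles: dict[int, str] | None = None) -> MultiChannelScene:
    """Read a TIFF scene; channel roles come from the sidecar or the caller."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    side = sidecar_path(path)
    meta = json.loads(side.read_text()) if side.exists() else None

    if meta is not None:
        shape = tuple(meta["shape"])
        if int(np.prod(shape[:-2])) != pages.shape[0] or tuple(shape[-2:]) != pages.shape[1:]:
            raise ParameterError(
                f"TIFF pages {pages.shape} inconsistent with sidecar shape {shape}"
            )
        pixels = pages.reshape(shape)
        roles = {int(k): v for k, v in meta["channel_roles"].items()}
        scene = MultiChannelScene(
            pixels=pixels.astype(float),
            channel_roles=roles,
            pixel_size_um=meta.get("pixel_size_um"),
            z_step_um=meta.get("z_step_um"),
            scene_id=meta.get("scene_id", path.stem),
        )
        return scene

    if channel_roles is None:
        raise ParameterError(f"no sidecar for {path} and no channel_roles given")
    n_channels = len(channel_roles)
    if pages.shape[0] % n_channels != 0:
        orphans = pages.shape[0] % n_channels
        raise ParameterError(
            f"{pages.shape[0]} TIFF pages do not divide into {n_channels} channels "
            f"({orphans} orphan page(s))"
        )
    for role in channel_roles.values():
        if role not in VALID_ROLES:
            raise ParameterError(f"unknown channel role {role!r}")
    n_z = pages.shape[0] // n_channels
    pixels = pages.reshape((n_z, n_channels) + pages.shape[1:])
    if n_z == 1:
        pixels = pixels[0]
    return MultiChannelScene(
        pixels=pixels.astype(float), channel_roles=dict(channel_roles),
        scene_id=path.stem,
    )


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file") from exc
    if df.empty:
        raise TableFormatError(f"{path}: no data rows")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a long-form ``group,category,count`` CSV into a count matrix.

    Duplicate (group, category) rows are summed with a warning; negative or
    non-numeric counts raise :class:`TableFormatError` with the row number.
    """
    df = _read_csv(path)
    required = {"group", "category", "count"}
    if not required.issubset(df.columns):
        raise TableFormatError(f"{path}: needs columns {sorted(required)}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise TableFormatError(
            f"{path}: invalid count at row(s) {[int(i) + 2 for i in bad]}"
        )
    df = df.assign(count=counts.astype(int))
    if df.duplicated(["group", "category"]).any():
        warnings.warn(f"{path}: duplicate (group, category) rows summed", UserWarning)
        df = df.groupby(["group", "category"], sort=False, as_index=False)["count"].sum()
    wide = df.pivot(index="group", columns="category", values="count")
    wide = wide.loc[df["group"].unique(), df["category"].unique()]
    wide.index.name = None
    wide.columns.name = None
    if wide.isna().any().any():
        raise TableFormatError(f"{path}: missing (group, category) combinations")
    return wide.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    """Write a count matrix back to the long ``group,category,count`` form."""
    long = counts.stack().rename("count").rename_axis(["group", "category"]).reset_index()
    long.to_csv(path, index=False)
    return Path(path)


def read_values(path: str | Path) -> dict[str, np.ndarray]:
    """Read a long ``group,replicate,value`` CSV into grouped value arrays."""
    df = _read_csv(path)
    required = {"group", "value"}
    if not required.issubset(df.columns):
        raise TableFormatError(f"{path}: needs columns {sorted(required)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        raise TableFormatError(
            f"{path}: non-numeric value at row(s) {[int(i) + 2 for i in bad]}"
        )
    df = df.assign(value=vals)
    return {str(g): sub["value"].to_numpy() for g, sub in df.groupby("group", sort=False)}


def write_report(reports: dict, path: str | Path) -> Path:
    """Write one or more StatReports (by endpoint name) as JSON."""
    payload = {
        name: (rep.to_dict() if hasattr(rep, "to_dict") else rep)
        for name, rep in reports.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))
    return Path(path)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
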