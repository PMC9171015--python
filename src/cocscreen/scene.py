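"""Multi-channel fluorescence scene container.

A :class:`MultiChannelScene` is the common image currency of the pipeline: a
nonnegative intensity array indexed ``(z, channel, y, x)`` (the z axis is
optional) plus a map from channel index to its biological role.  Intensities
are stored as floats and written to disk as 16-bit TIFF; no normalisation is
ever applied, raw values are preserved end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Channel roles understood by the analysis stages.
VALID_ROLES = frozenset({"hoechst", "tunel", "ethd1", "mito", "brightfield"})


@dataclass
class MultiChannelScene:
    """One imaged field: pixels + channel-role map.

    Parameters
    ----------
    pixels
        Array of shape ``(c, y, x)`` or ``(z, c, y, x)`` with nonnegative
        intensities (arbitrary units, as acquired).
    channel_roles
        Map channel index -> role, each role one of :data:`VALID_ROLES`.
    pixel_size_um
        Optional lateral pixel size in micrometres.
    z_step_um
        Optional z spacing in micrometres (confocal step size).
    """

    pixels: np.ndarray
    channel_roles: dict[int, str]
    pixel_size_um: float | None = None
    z_step_um: float | None = None
    scene_id: str = field(default="scene")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (3, 4):
            raise ParameterError(
                f"pixels must be (c, y, x) or (z, c, y, x); got ndim={self.pixels.ndim}"
            )
        if self.pixels.size == 0:
            raise ParameterError("scene has no pixels")
        if float(self.pixels.min()) < 0:
            raise ParameterError("intensities must be nonnegative")
        n_channels = self.pixels.shape[-3]
        if not self.channel_roles:
            raise ParameterError("at least one channel role is required")
        for idx, role in self.channel_roles.items():
            if not (0 <= int(idx) < n_channels):
                raise ParameterError(f"channel index {idx} out of range (n={n_channels})")
            if role not in VALID_ROLES:
                raise ParameterError(f"unknown channel role {role!r}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0] if self.has_z else 1

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[-3]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self.pixels.shape[-2:])  # type: ignore[return-value]

    # -- access -----------------------------------------------------------
    def channel_index(self, role: str) -> int:
        """Return the index of the first channel with the given role."""
        for idx, r in sorted(self.channel_roles.items()):
            if r == role:
                return int(idx)
        raise ParameterError(f"scene has no {role!r} channel")

    def plane(self, role: str, z: int = 0) -> np.ndarray:
        """Return one 2-D ``(y, x)`` plane for a channel role."""
        c = self.channel_index(role)
        if self.has_z:
            return self.pixels[z, c]
        if z != 0:
            raise ParameterError("scene has no z axis")
        return self.pixels[c]

    def stack(self, role: str) -> np.ndarray:
        """Return the full ``(z, y, x)`` stack for a channel role."""
        c = self.channel_index(role)
        if self.has_z:
            return self.pixels[:, c]
        return self.pixels[c][None]
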