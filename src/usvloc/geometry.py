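"""Scene geometry: coordinate frames, microphone arrays, and travel times.

All positions are expressed in a platform-centred world frame: origin at the
centre of the platform surface, x along the long (400 mm) edge, y along the
short (300 mm) edge, z up, z = 0 on the platform surface.  Lengths are in
millimetres, times in seconds, rates in Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: Speed of sound in dry air at 20 degC, mm/s.
SPEED_OF_SOUND_MM_S = 343_000.0

#: Golden angle in radians (sunflower / Vogel spiral parametrization).
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def as_point3(p: Iterable[float]) -> np.ndarray:
    """Coerce to a finite float (3,) array (z defaults to 0 for 2D input)."""
    a = np.asarray(p, dtype=float).ravel()
    if a.size == 2:
        a = np.append(a, 0.0)
    if a.size != 3 or not np.all(np.isfinite(a)):
        raise ValueError(f"expected a finite 2D/3D point, got {p!r}")
    return a


@dataclass(frozen=True)
class MicArrayGeometry:
    """Positions of one microphone set.

    Parameters
    ----------
    positions : (n_mics, 3) array, mm, world frame.
    label : short name of the set ("cam64" for the 64-channel MEMS array,
        "usm4" for the four peripheral condenser microphones).
    """

    positions: np.ndarray
    label: str

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[0] < 1 or pos.shape[1] != 3 or not np.all(np.isfinite(pos)):
            raise ValueError("mic positions must be a finite (n, 3) array")
        object.__setattr__(self, "positions", pos)

    @property
    def n_mics(self) -> int:
        return self.positions.shape[0]

    @property
    def aperture(self) -> float:
        """Largest pairwise mic distance, mm."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).max())


@dataclass(frozen=True)
class PlatformSpec:
    """Interaction platform and the beamforming surface above it.

    The beamforming surface extends the platform by ``margin`` on every edge
    and sits ``z_plane`` above the platform surface, parallel to it.
    """

    length_x: float = 400.0
    length_y: float = 300.0
    margin: float = 50.0
    z_plane: float = 10.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """Platform bounds (x_lo, x_hi, y_lo, y_hi), mm."""
        return (-self.length_x / 2, self.length_x / 2,
                -self.length_y / 2, self.length_y / 2)

    @property
    def beamform_bounds(self) -> tuple[float, float, float, float]:
        """Beamforming-surface bounds (platform + margin), mm."""
        x0, x1, y0, y1 = self.bounds
        m = self.margin
        return (x0 - m, x1 + m, y0 - m, y1 + m)

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        xy = np.atleast_2d(xy)
        x0, x1, y0, y1 = self.bounds
        return ((xy[:, 0] >= x0 - margin) & (xy[:, 0] <= x1 + margin)
                & (xy[:, 1] >= y0 - margin) & (xy[:, 1] <= y1 + margin))


@dataclass(frozen=True)
class CameraSpec:
    """Overhead camera: pixel grid, scale and placement.

    ``offset_x`` is the world x of the optical-axis ground point (the camera
    hangs to the left of the platform midpoint, hence the negative default);
    the sign convention is configurable by simply supplying another value.
    """

    width_px: int = 640
    height_px: int = 512
    mm_per_px: float = 0.815
    offset_x: float = -44.8
    offset_y: float = 0.0
    frame_interval_s: float = 0.018


@dataclass(frozen=True)
class SceneConfig:
    """Full static description of a recording scene."""

    platform: PlatformSpec = field(default_factory=PlatformSpec)
    arrays: dict[str, MicArrayGeometry] = field(default_factory=dict)
    camera: CameraSpec = field(default_factory=CameraSpec)
    speed_of_sound: float = SPEED_OF_SOUND_MM_S
    sample_rate: float = 250_000.0

    def __post_init__(self):
        if self.speed_of_sound <= 0:
            raise ValueError("speed of sound must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def cam64(self) -> MicArrayGeometry:
        return self.arrays["cam64"]

    @property
    def usm4(self) -> MicArrayGeometry:
        return self.arrays["usm4"]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "platform": vars(self.platform).copy(),
            "arrays": {
                k: {"label": a.label, "positions": a.positions.tolist()}
                for k, a in self.arrays.items()
            },
            "camera": vars(self.camera).copy(),
            "speed_of_sound": self.speed_of_sound,
            "sample_rate": self.sample_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(
            platform=PlatformSpec(**d["platform"]),
            arrays={
                k: MicArrayGeometry(np.asarray(v["positions"]), v["label"])
                for k, v in d["arrays"].items()
            },
            camera=CameraSpec(**d["camera"]),
            speed_of_sound=d["speed_of_sound"],
            sample_rate=d["sample_rate"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fermat_spiral_positions(n: int, diameter: float,
                            center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Sunflower (Vogel) spiral of ``n`` coplanar points inside a circle.

    Point k (1-based) sits at radius ``R * sqrt(k / n)`` and angle
    ``(k - 1) * golden_angle``, so the outermost point reaches exactly the
    circle radius ``R = diameter / 2`` and the packing is approximately
    uniform in area — the standard model for a Fermat-spiral mic array.

    Returns an (n, 3) array at ``center.z``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    c = as_point3(center)
    k = np.arange(1, n + 1)
    r = (diameter / 2.0) * np.sqrt(k / n)
    theta = (k - 1) * GOLDEN_ANGLE
    out = np.empty((n, 3))
    out[:, 0] = c[0] + r * np.cos(theta)
    out[:, 1] = c[1] + r * np.sin(theta)
    out[:, 2] = c[2]
    return out


def propagation_delay(source, mic, c: float = SPEED_OF_SOUND_MM_S):
    """Acoustic travel time source -> microphone, in seconds.

    Both arguments may be single points or (n, 3) arrays (broadcast).
    """
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    s = np.atleast_2d(np.asarray(source, dtype=float))
    m = np.atleast_2d(np.asarray(mic, dtype=float))
    d = np.sqrt(((s[:, None, :] - m[None, :, :]) ** 2).sum(-1)) / c
    if d.shape == (1, 1):
        return float(d[0, 0])
    return np.squeeze(d)


def default_scene() -> SceneConfig:
    """Scene with the reference recording geometry.

    40 x 30 cm platform; 64-mic Fermat-spiral array over a ~16 cm circle at
    +465 mm height, shifted +65.2 mm along the long axis; four peripheral
    microphones 50/60 mm beyond the platform corners at +121 mm; overhead
    camera 640 x 512 px at ~0.815 mm/px, shifted -44.8 mm.
    """
    platform = PlatformSpec()
    cam64 = MicArrayGeometry(
        fermat_spiral_positions(64, 160.0, center=(65.2, 0.0, 465.0)),
        label="cam64",
    )
    hx = platform.length_x / 2 + 50.0
    hy = platform.length_y / 2 + 60.0
    usm4 = MicArrayGeometry(
        np.array([[-hx, -hy, 121.0], [hx, -hy, 121.0],
                  [-hx, hy, 121.0], [hx, hy, 121.0]]),
        label="usm4",
    )
    return SceneConfig(platform=platform, arrays={"cam64": cam64, "usm4": usm4})


# -- planar scan grids ----------------------------------------------------

def grid_axis(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Node-centred axis with inclusive endpoints (lo and hi are nodes)."""
    n = int(round((hi - lo) / spacing)) + 1
    return lo + spacing * np.arange(n)


def world_to_index(x, origin: float, spacing: float):
    """Nearest grid index of world coordinate(s); exact on grid nodes."""
    return np.rint((np.asarray(x, dtype=float) - origin) / spacing).astype(int)


def index_to_world(i, origin: float, spacing: float):
    return origin + spacing * np.asarray(i, dtype=float)


def grid_nodes(x_axis: np.ndarray, y_axis: np.ndarray) -> np.ndarray:
    """All (x, y) nodes of the grid, shape (len(y)*len(x), 2), row-major in y."""
    xx, yy = np.meshgrid(x_axis, y_axis)
    return np.column_stack([xx.ravel(), yy.ravel()])
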