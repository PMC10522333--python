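"""Camera model: radial/tangential lens distortion and pixel<->world mapping.

Pixel coordinates are 0-based, origin at the top-left corner, y pointing
down (image convention); the world conversion flips y.  The distortion
formulas are applied literally in their printed forward form (undistorted ->
distorted); inverses are numeric.  Default parameters are identity-like
(large radial strength, zero tangential strengths): synthetic tracks bypass
distortion unless a fitted model is configured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import CameraSpec


@dataclass(frozen=True)
class DistortionModel:
    """Radial + tangential lens distortion parameters (pixels)."""

    center_x: float = 320.0         # radial distortion centre
    center_y: float = 256.0
    lam: float = 1e6                # radial strength (larger = weaker)
    zoom_x: float = 1.0
    zoom_y: float = 1.0
    tan_center_x: float = 320.0
    tan_center_y: float = 256.0
    kappa_x: float = 0.0            # tangential strengths
    kappa_y: float = 0.0
    platform_px: float = 491.0      # platform size in the undistorted image
    platform_py: float = 368.0
    platform_dx: float = 74.0       # platform offset from the top-left corner
    platform_dy: float = 72.0
    image_w: float = 640.0
    image_h: float = 512.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("radial strength lambda must be positive")


def _atanc(u):
    """atan(u)/u with the u -> 0 limit of 1."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    nz = u != 0
    out[nz] = np.arctan(u[nz]) / u[nz]
    return out


def apply_radial(point, model: DistortionModel):
    """Forward radial distortion: undistorted -> distorted pixels."""
    p = np.atleast_2d(np.asarray(point, dtype=float))
    dx = p[:, 0] - model.center_x
    dy = p[:, 1] - model.center_y
    rd = np.hypot(dx, dy)
    fac = _atanc(rd / model.lam)
    out = np.column_stack([
        model.center_x + fac * dx * model.zoom_x,
        model.center_y + fac * dy * model.zoom_y,
    ])
    return out[0] if np.asarray(point).ndim == 1 else out


def invert_radial(point_distorted, model: DistortionModel,
                  tol: float = 1e-9):
    """Numeric inverse of the radial map (per-point 1D root find)."""
    p = np.atleast_2d(np.asarray(point_distorted, dtype=float))
    out = np.empty_like(p)
    for k, (xd, yd) in enumerate(p):
        dx = (xd - model.center_x) / model.zoom_x
        dy = (yd - model.center_y) / model.zoom_y
        rz = np.hypot(dx, dy)      # = atanc(ru/lam) * ru, monotone in ru
        if rz == 0:
            out[k] = (model.center_x, model.center_y)
            continue
        g = lambda ru: _atanc(np.array([ru / model.lam]))[0] * ru - rz
        hi = rz * 2
        while g(hi) < 0:
            hi *= 2
        ru = brentq(g, rz * 0.5, hi, xtol=tol)
        s = ru / rz
        out[k] = (model.center_x + s * dx, model.center_y + s * dy)
    return out[0] if np.asarray(point_distorted).ndim == 1 else out


def apply_tangential(point, model: DistortionModel):
    """Forward tangential distortion: undistorted -> distorted pixels."""
    p = np.atleast_2d(np.asarray(point, dtype=float))
    xu, yu = p[:, 0], p[:, 1]
    xd = xu - (xu - model.tan_center_x) / abs(model.image_w - model.tan_center_x) \
        * model.kappa_x / model.platform_py * (yu - model.platform_dy) * model.zoom_x
    yd = yu - (yu - model.tan_center_y) / abs(model.image_h - model.tan_center_y) \
        * model.kappa_y / model.platform_px * (xu - model.platform_dx) * model.zoom_y
    out = np.column_stack([xd, yd])
    return out[0] if np.asarray(point).ndim == 1 else out


def invert_tangential(point_distorted, model: DistortionModel,
                      tol: float = 1e-9, max_iter: int = 100):
    """Numeric inverse via fixed-point iteration."""
    p = np.atleast_2d(np.asarray(point_distorted, dtype=float))
    u = p.copy()
    for _ in range(max_iter):
        fwd = np.atleast_2d(apply_tangential(u, model))
        err = p - fwd
        u = u + err
        if np.abs(err).max() < tol:
            break
    return u[0] if np.asarray(point_distorted).ndim == 1 else u


def undistort(point_distorted, model: DistortionModel):
    """Full correction: distorted pixels -> undistorted pixels.

    The correction pipeline inverts the forward maps in composition order
    (radial applied first, then tangential).
    """
    return invert_radial(invert_tangential(point_distorted, model), model)


def distort(point_undistorted, model: DistortionModel):
    return apply_tangential(apply_radial(point_undistorted, model), model)


# ---------------------------------------------------------------------------
# pixel <-> world

def px_to_world(point_px, camera: CameraSpec):
    """Undistorted pixel -> platform-centred world coordinates (mm).

    The image centre pixel looks straight down at the camera's ground point
    (``offset_x``, ``offset_y``); image y points down so world y is flipped.
    """
    p = np.atleast_2d(np.asarray(point_px, dtype=float))
    wx = (p[:, 0] - camera.width_px / 2) * camera.mm_per_px + camera.offset_x
    wy = -(p[:, 1] - camera.height_px / 2) * camera.mm_per_px + camera.offset_y
    out = np.column_stack([wx, wy])
    return out[0] if np.asarray(point_px).ndim == 1 else out


def world_to_px(point_mm, camera: CameraSpec):
    p = np.atleast_2d(np.asarray(point_mm, dtype=float))
    px = (p[:, 0] - camera.offset_x) / camera.mm_per_px + camera.width_px / 2
    py = -(p[:, 1] - camera.offset_y) / camera.mm_per_px + camera.height_px / 2
    out = np.column_stack([px, py])
    return out[0] if np.asarray(point_mm).ndim == 1 else out


def frame_at(time_s: float, frame_triggers: np.ndarray) -> int:
    """Nearest frame-trigger index; exact ties go to the earlier frame."""
    t = np.asarray(frame_triggers, dtype=float)
    if time_s < t[0] or time_s > t[-1]:
        raise ValueError(f"time {time_s} s outside the frame clock")
    i = int(np.searchsorted(t, time_s))
    if i == 0:
        return 0
    return i - 1 if time_s - t[i - 1] <= t[i] - time_s else i
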