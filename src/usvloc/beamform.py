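"""Delay-and-sum beamforming on the 64-channel overhead array.

The sound field over the platform plane is the steered-response power

    P(x, y) = sum_f | sum_m S_m(f) * exp(+i 2 pi f tau(m, x, y, z)) |^2

where ``S_m`` is the spectrum of the call snippet on channel m and ``tau``
the propagation delay from the grid node to that microphone: the steering
phases conjugate-cancel the propagation delays, so signals from the true
origin add coherently.  Localization is a two-step scan: a coarse 10 mm
grid over the whole beamforming surface, then a fine 1 mm grid over a
30 x 30 mm window centred on the coarse peak; the call origin is the
power-weighted centroid of the fine window.  Per call, a signal-to-noise
ratio max/std of the coarse field grades estimate quality; its inverse is
the (uncalibrated) localization uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq

from .geometry import SceneConfig, grid_axis, grid_nodes
from .preprocess import ClockMap, UsvSegment
from .recording import MultiChannelRecording

COARSE_SPACING_MM = 10.0
FINE_SPACING_MM = 1.0
FINE_WINDOW_MM = 30.0
DEFAULT_MAX_FREQS = 64


@dataclass
class SoundFieldEstimate:
    """Steered-power values on a planar scan grid."""

    x_axis: np.ndarray          # (nx,) node x coordinates, mm
    y_axis: np.ndarray          # (ny,)
    values: np.ndarray          # (ny, nx), >= 0
    peak_xy: np.ndarray         # (2,) argmax node
    centroid_xy: np.ndarray     # (2,) power-weighted centroid
    snr: float                  # max / std over nodes (inf if degenerate)

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.snr)


@dataclass
class LocalizationEstimate:
    """Planar origin of one call with a scalar uncertainty."""

    origin: np.ndarray          # (2,) mm
    uncertainty: float          # method-intrinsic scale; calibrated to mm later
    method: str                 # "cam64" | "slim"
    snr: float | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.uncertainty <= 0:
            raise ValueError("uncertainty must be positive")


def steered_power_map(spectra: np.ndarray, freqs: np.ndarray,
                      mic_positions: np.ndarray, nodes_xy: np.ndarray,
                      z_plane: float, c: float,
                      chunk: int = 16) -> np.ndarray:
    """Steered-response power at each node for the given frequency set.

    ``spectra`` is (n_mics, n_freqs) complex; returns (n_nodes,) >= 0.
    """
    spectra = np.asarray(spectra, dtype=complex)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency set")
    if mic_positions.shape[0] < 1:
        raise ValueError("need at least one microphone")
    nodes3 = np.column_stack([nodes_xy, np.full(len(nodes_xy), z_plane)])
    tau = np.sqrt(((nodes3[:, None, :] - mic_positions[None, :, :]) ** 2)
                  .sum(-1)) / c                                      # (n, m)
    df = np.diff(freqs)
    if len(freqs) > 2 and np.allclose(df, df[0], rtol=0, atol=1e-9):
        # evenly spaced bins: one exp, then per-bin phase recursion
        power = np.zeros(len(nodes_xy))
        E = np.exp(2j * np.pi * freqs[0] * tau)
        Estep = np.exp(2j * np.pi * df[0] * tau)
        for k in range(len(freqs)):
            if k:
                E *= Estep
            beam = E @ spectra[:, k]
            power += beam.real**2 + beam.imag**2
        return power
    power = np.zeros(len(nodes_xy))
    for k0 in range(0, len(freqs), chunk):
        fc = freqs[k0:k0 + chunk]
        sc = spectra[:, k0:k0 + chunk]
        phase = np.exp(2j * np.pi * tau[:, :, None] * fc[None, None, :])
        beam = np.einsum("nmf,mf->nf", phase, sc)
        power += (beam.real**2 + beam.imag**2).sum(axis=1)
    return power


def segment_spectra(segment: UsvSegment, rec: MultiChannelRecording,
                    clock_map: ClockMap | None = None,
                    max_freqs: int = DEFAULT_MAX_FREQS):
    """Per-channel spectra of the call snippet at in-band FFT bins.

    The snippet is the whole call interval (rectangular window); the
    frequency set is the FFT bins inside the call's [f_lo, f_hi] band,
    decimated evenly to at most ``max_freqs`` bins.  ``clock_map`` maps the
    segment's clock to this recording's clock.
    """
    t0, t1 = segment.onset, segment.offset
    if clock_map is not None:
        t0, t1 = clock_map.apply(t0), clock_map.apply(t1)
    if t0 < 0 or t1 > rec.duration:
        raise ValueError("segment lies outside this recording")
    x = rec.slice_seconds(t0, t1).astype(np.float64)
    n = x.shape[1]
    X = rfft(x, axis=1)
    f = rfftfreq(n, 1 / rec.sample_rate)
    idx = np.flatnonzero((f >= segment.f_lo) & (f <= segment.f_hi))
    if idx.size == 0:
        raise ValueError("no FFT bins inside the call band")
    if idx.size > max_freqs:
        # uniform-stride decimation keeps the bin spacing exactly even
        idx = idx[::int(np.ceil(idx.size / max_freqs))]
    return X[:, idx], f[idx]


def _field_estimate(x_axis, y_axis, power,
                    local_radius: int | None = None) -> SoundFieldEstimate:
    """Field container; with ``local_radius`` (in nodes) the centroid is
    the local weighted average over that neighbourhood of the argmax (the
    mainlobe), which excludes the sidelobe pedestal of the window."""
    values = power.reshape(len(y_axis), len(x_axis))
    iy, ix = np.unravel_index(np.argmax(values), values.shape)
    peak = np.array([x_axis[ix], y_axis[iy]])
    if local_radius is None:
        sub, xs, ys = values, x_axis, y_axis
    else:
        r = local_radius
        sub = values[max(0, iy - r):iy + r + 1, max(0, ix - r):ix + r + 1]
        xs = x_axis[max(0, ix - r):ix + r + 1]
        ys = y_axis[max(0, iy - r):iy + r + 1]
    w = sub.sum()
    if w > 0:
        cx = (sub.sum(axis=0) * xs).sum() / w
        cy = (sub.sum(axis=1) * ys).sum() / w
        centroid = np.array([cx, cy])
    else:
        centroid = peak.copy()
    sd = float(values.std())
    snr = float(values.max() / sd) if sd > 0 else np.inf
    return SoundFieldEstimate(x_axis=x_axis, y_axis=y_axis, values=values,
                              peak_xy=peak, centroid_xy=centroid, snr=snr)


def coarse_scan(segment: UsvSegment, rec: MultiChannelRecording,
                scene: SceneConfig, clock_map: ClockMap | None = None,
                spacing: float = COARSE_SPACING_MM,
                max_freqs: int = DEFAULT_MAX_FREQS) -> SoundFieldEstimate:
    """Steered power over the full beamforming surface (default 10 mm grid)."""
    spectra, freqs = segment_spectra(segment, rec, clock_map, max_freqs)
    x0, x1, y0, y1 = scene.platform.beamform_bounds
    xa, ya = grid_axis(x0, x1, spacing), grid_axis(y0, y1, spacing)
    power = steered_power_map(spectra, freqs, scene.cam64.positions,
                              grid_nodes(xa, ya), scene.platform.z_plane,
                              scene.speed_of_sound)
    return _field_estimate(xa, ya, power)


def fine_scan(segment: UsvSegment, rec: MultiChannelRecording,
              scene: SceneConfig, center,
              clock_map: ClockMap | None = None,
              spacing: float = FINE_SPACING_MM,
              window: float = FINE_WINDOW_MM,
              max_freqs: int = DEFAULT_MAX_FREQS,
              centroid_radius_mm: float = 5.0) -> SoundFieldEstimate:
    """Steered power on a fine window centred on ``center`` (coarse peak).

    The window is clipped at the beamforming-surface boundary.  The final
    call origin is the field's ``centroid_xy``: the local power-weighted
    average over the mainlobe (cells within ``centroid_radius_mm`` of the
    fine argmax) — averaging over the whole window would let the sidelobe
    pedestal drag the origin toward the window centre.
    """
    spectra, freqs = segment_spectra(segment, rec, clock_map, max_freqs)
    bx0, bx1, by0, by1 = scene.platform.beamform_bounds
    cx, cy = float(center[0]), float(center[1])
    h = window / 2
    xa = grid_axis(max(bx0, cx - h), min(bx1, cx + h), spacing)
    ya = grid_axis(max(by0, cy - h), min(by1, cy + h), spacing)
    power = steered_power_map(spectra, freqs, scene.cam64.positions,
                              grid_nodes(xa, ya), scene.platform.z_plane,
                              scene.speed_of_sound)
    return _field_estimate(xa, ya, power,
                           local_radius=int(round(centroid_radius_mm
                                                  / spacing)))


def field_snr(field: SoundFieldEstimate) -> float:
    """max/std quality index of a (coarse) sound field."""
    if field.values.size < 2:
        raise ValueError("need at least two grid nodes")
    return field.snr


def localize_cam64(segment: UsvSegment, rec: MultiChannelRecording,
                   scene: SceneConfig, clock_map: ClockMap | None = None,
                   max_freqs: int = DEFAULT_MAX_FREQS
                   ) -> LocalizationEstimate | None:
    """Two-step beamforming localization of one call.

    Returns None when the call lies outside the recording window or the
    field is degenerate.  ``uncertainty`` is 1/SNR of the coarse field (a
    unitless proxy; calibrated to millimetres downstream).
    """
    try:
        coarse = coarse_scan(segment, rec, scene, clock_map,
                             max_freqs=max_freqs)
    except ValueError:
        return None
    if coarse.degenerate:
        return None
    fine = fine_scan(segment, rec, scene, coarse.peak_xy, clock_map,
                     max_freqs=max_freqs)
    return LocalizationEstimate(origin=fine.centroid_xy,
                                uncertainty=1.0 / coarse.snr,
                                method="cam64", snr=coarse.snr)
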