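"""Four-microphone TDOA localization (SLIM-style).

For each of the six microphone pairs, the time difference of arrival
(generalized cross-correlation, PHAT-weighted by default, with parabolic
sub-sample interpolation) constrains the source to a constant
range-difference curve (a hyperbola branch) on the platform plane.  Each
usable pair's curve is rasterized onto a 1 mm accumulation grid with a
Gaussian cross-section kernel; the summed intersection density peaks at the
source.  The estimate's uncertainty is the standard deviation of all grid
positions whose density exceeds 90% of the maximum (floored at 1 mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.fft import irfft, rfft

from .beamform import LocalizationEstimate
from .geometry import SceneConfig, grid_axis, propagation_delay
from .preprocess import ClockMap, UsvSegment, band_filter_fft
from .recording import MultiChannelRecording

GRID_SPACING_MM = 1.0
KERNEL_SIGMA_MM = 2.0
UNCERTAINTY_FLOOR_MM = 1.0
DENSITY_FRACTION = 0.9


def pairwise_tdoa(x_i: np.ndarray, x_j: np.ndarray, sample_rate: float,
                  max_delay: float, weighting: str = "phat",
                  band: tuple[float, float] | None = None,
                  min_peak_ratio: float = 4.0) -> float | None:
    """TDOA between two snippets on a common clock, seconds.

    Positive values mean the sound arrives at mic i first.  Uses the
    generalized cross-correlation ("phat" weighting by default, "cc" for
    plain cross-correlation) with parabolic sub-sample interpolation,
    clamped to +/- ``max_delay``.  With ``band`` set, only cross-spectrum
    bins inside the band contribute; PHAT additionally discards bins far
    below the peak magnitude (whitening leakage bins would swamp the
    correlation with noise).  Returns None when the correlation has no
    clear peak (below ``min_peak_ratio`` standard deviations).
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    n = len(x_i) + len(x_j)
    Xi, Xj = rfft(x_i, n), rfft(x_j, n)
    G = Xi * np.conj(Xj)
    if band is not None:
        f = np.arange(len(G)) * sample_rate / n
        G[(f < band[0]) | (f > band[1])] = 0
    if weighting == "phat":
        mag = np.abs(G)
        keep = mag > 1e-6 * mag.max()
        G[keep] /= mag[keep]
        G[~keep] = 0
    elif weighting != "cc":
        raise ValueError(f"unknown GCC weighting {weighting!r}")
    cc = irfft(G, n)
    lags = np.fft.fftfreq(n, 1 / n).astype(int)       # sample lags per bin
    max_lag = int(np.ceil(max_delay * sample_rate))
    keep = np.abs(lags) <= max_lag
    cc_w, lags_w = cc[keep], lags[keep]
    order = np.argsort(lags_w)
    cc_w, lags_w = cc_w[order], lags_w[order]
    k = int(np.argmax(cc_w))
    sd = cc_w.std()
    if sd <= 0 or (cc_w[k] - cc_w.mean()) / sd < min_peak_ratio:
        return None
    # parabolic sub-sample refinement
    lag = float(lags_w[k])
    if 0 < k < len(cc_w) - 1:
        y0, y1, y2 = cc_w[k - 1], cc_w[k], cc_w[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += 0.5 * (y0 - y2) / denom
    # positive lag of argmax of sum x_i[t] x_j[t+lag] means x_j leads;
    # arrival at i first corresponds to x_j delayed, i.e. negative lag here
    return float(np.clip(-lag / sample_rate, -max_delay, max_delay))


@dataclass
class OriginCurveSet:
    """Accumulated origin-curve density for one call."""

    x_axis: np.ndarray
    y_axis: np.ndarray
    density: np.ndarray             # (ny, nx)
    tdoas: dict[tuple[int, int], float]
    n_pairs_used: int


class SlimLocalizer:
    """TDOA localizer bound to one scene (precomputes pair range fields)."""

    def __init__(self, scene: SceneConfig, spacing: float = GRID_SPACING_MM,
                 kernel_sigma: float = KERNEL_SIGMA_MM,
                 weighting: str = "phat"):
        self.scene = scene
        self.spacing = spacing
        self.kernel_sigma = kernel_sigma
        self.weighting = weighting
        x0, x1, y0, y1 = scene.platform.beamform_bounds
        self.x_axis = grid_axis(x0, x1, spacing)
        self.y_axis = grid_axis(y0, y1, spacing)
        xx, yy = np.meshgrid(self.x_axis, self.y_axis)
        nodes = np.column_stack([xx.ravel(), yy.ravel(),
                                 np.full(xx.size, scene.platform.z_plane)])
        mics = scene.usm4.positions
        c = scene.speed_of_sound
        self.pairs = list(combinations(range(len(mics)), 2))
        # range difference d(p, mic_i) - d(p, mic_j) per node, mm
        self._ddiff = {}
        dist = propagation_delay(nodes, mics, c) * c       # (n_nodes, n_mics)
        for (i, j) in self.pairs:
            self._ddiff[(i, j)] = (dist[:, i] - dist[:, j]).reshape(
                xx.shape).astype(np.float32)
        self._mics = mics
        self._c = c

    def curve_density(self, tdoa: float, i: int, j: int) -> np.ndarray | None:
        """Gaussian-rasterized origin curve of one pair (None if unphysical).

        The kernel is applied to the range-difference residual in mm; with
        positive TDOA meaning arrival at mic i first, the curve satisfies
        d(p, i) - d(p, j) = -c * tdoa.
        """
        baseline = np.linalg.norm(self._mics[i] - self._mics[j])
        if abs(tdoa * self._c) >= baseline:
            return None
        ddiff = self._ddiff[(i, j)] if (i, j) in self._ddiff \
            else -self._ddiff[(j, i)]
        resid = ddiff + np.float32(self._c * tdoa)
        return np.exp(-0.5 * (resid / self.kernel_sigma) ** 2)

    def localize(self, segment: UsvSegment, rec: MultiChannelRecording,
                 clock_map: ClockMap | None = None,
                 min_pairs: int = 3) -> LocalizationEstimate | None:
        curves = self.origin_curves(segment, rec, clock_map)
        if curves is None or curves.n_pairs_used < min_pairs:
            return None
        return estimate_from_density(curves)

    def origin_curves(self, segment: UsvSegment, rec: MultiChannelRecording,
                      clock_map: ClockMap | None = None
                      ) -> OriginCurveSet | None:
        t0, t1 = segment.onset, segment.offset
        if clock_map is not None:
            t0, t1 = clock_map.apply(t0), clock_map.apply(t1)
        if t0 < 0 or t1 > rec.duration:
            return None
        x = band_filter_fft(rec.slice_seconds(t0, t1), rec.sample_rate,
                            (segment.f_lo, segment.f_hi))
        max_delay = self.scene.usm4.aperture / self._c
        density = np.zeros_like(self._ddiff[self.pairs[0]], dtype=np.float64)
        tdoas, used = {}, 0
        for (i, j) in self.pairs:
            tdoa = pairwise_tdoa(x[i], x[j], rec.sample_rate, max_delay,
                                 weighting=self.weighting,
                                 band=(segment.f_lo, segment.f_hi))
            if tdoa is None:
                continue
            contrib = self.curve_density(tdoa, i, j)
            if contrib is None:
                continue
            density += contrib
            tdoas[(i, j)] = tdoa
            used += 1
        if used == 0:
            return None
        return OriginCurveSet(x_axis=self.x_axis, y_axis=self.y_axis,
                              density=density, tdoas=tdoas, n_pairs_used=used)


def estimate_from_density(curves: OriginCurveSet,
                          fraction: float = DENSITY_FRACTION,
                          floor_mm: float = UNCERTAINTY_FLOOR_MM
                          ) -> LocalizationEstimate:
    """Peak of the intersection density with the >90%-spread uncertainty."""
    d = curves.density
    iy, ix = np.unravel_index(np.argmax(d), d.shape)
    top = d > fraction * d.max()
    yy, xx = np.nonzero(top)
    w = d[yy, xx]
    px = curves.x_axis[xx]
    py = curves.y_axis[yy]
    # sub-cell refinement: density-weighted centroid of the top cells
    origin = np.array([np.average(px, weights=w), np.average(py, weights=w)])
    spread = float(np.sqrt(np.var(px) + np.var(py)))
    return LocalizationEstimate(origin=origin,
                                uncertainty=max(spread, floor_mm),
                                method="slim")


def localize_slim(segment: UsvSegment, rec: MultiChannelRecording,
                  scene: SceneConfig, clock_map: ClockMap | None = None,
                  localizer: SlimLocalizer | None = None
                  ) -> LocalizationEstimate | None:
    """One-shot TDOA localization (builds the grid; reuse SlimLocalizer in
    loops)."""
    localizer = localizer or SlimLocalizer(scene)
    return localizer.localize(segment, rec, clock_map)
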