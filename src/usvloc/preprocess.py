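"""Audio preprocessing: filtering, clock alignment, call detection, band rule.

Detection here is deliberately simple plumbing (spectrogram band-energy with
hysteresis); the scientific content of this module is the per-call frequency
band rule used to restrict beamforming, and the two-click clock alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import irfft, rfft, rfftfreq

from .recording import MultiChannelRecording

#: Analysis band of the peripheral microphones, Hz.
USM4_BAND = (30e3, 110e3)


@dataclass
class UsvSegment:
    """One detected vocalization, timed on the usm4 clock."""

    onset: float
    offset: float
    f_lo: float
    f_hi: float
    energy: float = 0.0

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class ClockMap:
    """Affine map between two recorder clocks: t_b = offset + drift * t_a."""

    offset: float
    drift: float = 1.0

    def __post_init__(self):
        if abs(self.drift - 1.0) >= 1e-3:
            raise ValueError("clock drift implausibly far from 1")

    def apply(self, t_a):
        return self.offset + self.drift * np.asarray(t_a, dtype=float)

    def invert(self) -> "ClockMap":
        return ClockMap(offset=-self.offset / self.drift, drift=1.0 / self.drift)


def align_clocks(click_times_a, click_times_b) -> ClockMap:
    """Fit t_b = offset + drift * t_a exactly through two click pairs."""
    a1, a2 = map(float, click_times_a)
    b1, b2 = map(float, click_times_b)
    if a2 == a1:
        raise ValueError("coincident clicks: cannot fit a clock map")
    drift = (b2 - b1) / (a2 - a1)
    return ClockMap(offset=b1 - drift * a1, drift=drift)


def bandpass_usm4(rec: MultiChannelRecording,
                  band: tuple[float, float] = USM4_BAND) -> MultiChannelRecording:
    """Zero-phase 30-110 kHz band-pass (order-20 IIR, forward-backward).

    A Butterworth band-pass of order 20 (10 biquad sections) applied with
    ``sosfiltfilt``: flat passband, >40 dB attenuation 10 kHz outside the
    band edges.
    """
    if rec.sample_rate < 2 * band[1]:
        raise ValueError("sample rate too low for the analysis band")
    sos = signal.butter(10, band, btype="bandpass", fs=rec.sample_rate,
                        output="sos")
    # channel-wise filtering keeps the transient memory footprint small
    out = np.empty_like(rec.data, dtype=rec.data.dtype)
    for ch in range(rec.n_channels):
        out[ch] = signal.sosfiltfilt(sos, rec.data[ch])
    return MultiChannelRecording(out, rec.sample_rate, rec.label)


def band_filter_fft(x: np.ndarray, fs: float,
                    band: tuple[float, float]) -> np.ndarray:
    """Brick-wall band-pass of short snippets via FFT masking."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n = x.shape[-1]
    X = rfft(x, axis=-1)
    f = rfftfreq(n, 1 / fs)
    X[..., (f < band[0]) | (f > band[1])] = 0
    return irfft(X, n, axis=-1)


# ---------------------------------------------------------------------------
# synchronization-click detection

def detect_clicks(rec: MultiChannelRecording,
                  search_s: float = 1.0) -> tuple[float, float]:
    """Times of the start and end synchronization clicks (local clock).

    Looks for the strongest short broadband transient within ``search_s`` of
    each end of the recording, on the channel-mean squared signal.
    """
    fs = rec.sample_rate
    p = (rec.data.astype(np.float64) ** 2).mean(axis=0)
    w = max(3, int(round(0.2e-3 * fs)))
    from scipy.ndimage import uniform_filter1d
    p = uniform_filter1d(p, w)
    n = len(p)
    ns = min(n // 2, int(search_s * fs))
    i1 = int(np.argmax(p[:ns]))
    i2 = n - ns + int(np.argmax(p[n - ns:]))
    return i1 / fs, i2 / fs


# ---------------------------------------------------------------------------
# detection

def _segments_from_mask(mask: np.ndarray, times: np.ndarray,
                        min_dur: float, merge_gap: float) -> list[tuple[float, float]]:
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    segs = [(times[a], times[b - 1]) for a, b in zip(starts, stops)]
    merged: list[list[float]] = []
    for a, b in segs:
        if merged and a - merged[-1][1] <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a >= min_dur]


def spectrogram_db(x: np.ndarray, fs: float, nperseg: int = 512,
                   overlap: float = 0.75):
    """Per-channel magnitude spectrogram in dB; returns (f, t, S_db)."""
    f, t, S = signal.spectrogram(np.atleast_2d(x), fs=fs, nperseg=nperseg,
                                 noverlap=int(nperseg * overlap),
                                 window="hann", mode="magnitude")
    return f, t, 20 * np.log10(S + 1e-12)


def detect_usvs(rec: MultiChannelRecording,
                band: tuple[float, float] = USM4_BAND,
                thresh_hi_db: float = 6.0, thresh_lo_db: float = 3.0,
                min_dur: float = 5e-3, merge_gap: float = 10e-3,
                max_dur: float = 0.3,
                nperseg: int = 512) -> list[UsvSegment]:
    """Spectrogram band-energy detector with hysteresis.

    A call only has to be detected on one of the channels (per-channel masks
    are OR-ed).  The statistic is the integrated in-band power per
    spectrogram frame, in dB over each channel's median-frame noise floor;
    onsets open at ``thresh_hi_db`` and extend while the excess stays above
    ``thresh_lo_db``.  Very long segments (> ``max_dur``) are discarded.
    """
    fs = rec.sample_rate
    rows = []
    for ch in range(rec.n_channels):           # one channel at a time
        f, t, S = signal.spectrogram(rec.data[ch], fs=fs, nperseg=nperseg,
                                     noverlap=int(nperseg * 0.75),
                                     window="hann", mode="psd")
        inband = (f >= band[0]) & (f <= band[1])
        rows.append(S[inband].sum(axis=0))     # frame band power
    p = np.asarray(rows)                       # (n_ch, n_frames)
    floor = np.median(p, axis=1, keepdims=True)
    excess = 10 * np.log10(p / (floor + 1e-30) + 1e-12)
    mask = np.zeros(excess.shape[1], dtype=bool)
    for ch in range(excess.shape[0]):
        hi = excess[ch] > thresh_hi_db
        lo = excess[ch] > thresh_lo_db
        m = np.zeros_like(hi)
        on = False
        for i in range(len(hi)):
            on = hi[i] or (on and lo[i])
            m[i] = on
        for i in range(len(hi) - 2, -1, -1):   # extend backwards to lo-onset
            if m[i + 1] and lo[i]:
                m[i] = True
        mask |= m
    if not mask.any():
        return []
    half_frame = (nperseg / 2) / fs
    segs = []
    for a, b in _segments_from_mask(mask, t, min_dur, merge_gap):
        a, b = a - half_frame, b + half_frame
        if b - a > max_dur:
            continue
        f_lo, f_hi = estimate_usv_band_from_rec(rec, a, b, nperseg=nperseg)
        seg = UsvSegment(onset=a, offset=b, f_lo=f_lo, f_hi=f_hi)
        seg.energy = usv_energy(seg, rec)
        segs.append(seg)
    return segs


# ---------------------------------------------------------------------------
# per-call frequency band

def estimate_usv_band(peak_freqs: np.ndarray,
                      broaden_hz: float = 5e3, cap_hz: float = 95e3,
                      wide_hz: float = 50e3,
                      wide_lo_hz: float = 45e3) -> tuple[float, float]:
    """Frequency band of one call from its per-frame peak frequencies.

    The 10th-90th percentile of the most intense frequency per spectrogram
    frame, broadened by 5 kHz at both ends, capped at 95 kHz at the top; if
    the resulting range exceeds 50 kHz the lower end is reset to 45 kHz
    (avoids sweeping in the low-frequency noise region on broad calls).
    """
    pf = np.asarray(peak_freqs, dtype=float).ravel()
    if pf.size == 0:
        raise ValueError("empty spectrogram: no peak frequencies")
    lo, hi = np.percentile(pf, [10, 90])
    lo, hi = lo - broaden_hz, hi + broaden_hz
    hi = min(hi, cap_hz)
    if hi - lo > wide_hz:
        lo = wide_lo_hz
    # keep a usable band even for ridges pressed against the 95 kHz cap
    lo = min(max(lo, 1e3), hi - broaden_hz)
    return float(lo), float(hi)


def estimate_usv_band_from_rec(rec: MultiChannelRecording, onset: float,
                               offset: float, band=USM4_BAND,
                               nperseg: int = 512) -> tuple[float, float]:
    x = rec.slice_seconds(onset, offset)
    f, t, S = spectrogram_db(x, rec.sample_rate,
                             nperseg=min(nperseg, x.shape[1]))
    inband = (f >= band[0]) & (f <= band[1])
    Smax = S[:, inband, :].max(axis=0)         # strongest channel per bin
    peak = f[inband][np.argmax(Smax, axis=0)]
    return estimate_usv_band(peak)


def usv_energy(seg: UsvSegment, rec: MultiChannelRecording) -> float:
    """Mean in-band RMS across channels over the call interval."""
    x = rec.slice_seconds(seg.onset, seg.offset)
    xb = band_filter_fft(x, rec.sample_rate, (seg.f_lo, seg.f_hi))
    return float(np.sqrt((xb ** 2).mean(axis=1)).mean())


# ---------------------------------------------------------------------------
# evaluation helper (plumbing for simulations)

def match_segments(segments: list[UsvSegment], ground_truth,
                   max_gap: float = 10e-3) -> list[int | None]:
    """Index of the ground-truth event overlapping each detected segment.

    Greedy by temporal overlap; None where nothing overlaps (within
    ``max_gap`` tolerance at the edges).
    """
    out: list[int | None] = []
    for seg in segments:
        best, best_ov = None, 0.0
        for k, ev in enumerate(ground_truth):
            ov = min(seg.offset, ev.offset + max_gap) - \
                max(seg.onset, ev.onset - max_gap)
            if ov > best_ov:
                best, best_ov = k, ov
        out.append(best)
    return out
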