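"""Synthetic acoustic scenes with ground truth.

Emulates the reference recording conditions: a 40 x 30 cm elevated platform
in an anechoic booth, a 64-channel MEMS spiral array overhead, four
high-quality ultrasonic microphones at the corners, mice moving on the
platform and emitting 30-110 kHz frequency-sweep vocalizations from their
snout positions.  Every generated quantity is ground-truthed, so the whole
localization/assignment pipeline can be validated end to end.

Technology-specific sensor noise: the MEMS-array model has a noise floor
rising ~6 dB/octave above a 60 kHz knee (the array's known weakness for
very-high-frequency calls); the peripheral-microphone model is spectrally
flat.  Propagation is anechoic: fractional-sample delays (FFT phase shift)
plus 1/r spherical spreading from an omnidirectional point source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.ndimage import gaussian_filter1d

from .geometry import MicArrayGeometry, SceneConfig, default_scene, propagation_delay
from .recording import MultiChannelRecording

#: Reference distance for spherical spreading: a source at 100 mm has gain 1.
R_REF_MM = 100.0

#: Distance from body centre to snout and to head-centre marker, mm.
HALF_BODY_MM = 12.5


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass
class UsvGroundTruth:
    """One scheduled vocalization with its true origin."""

    onset: float
    offset: float
    source: np.ndarray          # (3,) mm, world frame
    emitter_id: int
    f_start: float
    f_end: float
    amplitude: float = 1.0
    shape: str = "linear"
    overlaps: bool = False

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")
        self.source = np.asarray(self.source, dtype=float)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)

    def to_dict(self) -> dict:
        return {
            "onset": self.onset, "offset": self.offset,
            "source": list(map(float, self.source)),
            "emitter_id": self.emitter_id,
            "f_start": self.f_start, "f_end": self.f_end,
            "amplitude": self.amplitude, "shape": self.shape,
            "overlaps": self.overlaps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UsvGroundTruth":
        return cls(**{**d, "source": np.asarray(d["source"])})


@dataclass
class MouseTrack:
    """Per-frame pose of one mouse: snout and head-centre markers (mm)."""

    mouse_id: int
    sex: str
    t: np.ndarray               # (F,) strictly increasing frame times, s
    snout: np.ndarray           # (F, 2)
    head_center: np.ndarray     # (F, 2)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.snout = np.asarray(self.snout, dtype=float)
        self.head_center = np.asarray(self.head_center, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if np.any(np.all(self.snout == self.head_center, axis=1)):
            raise ValueError("snout and head-centre markers must not coincide")

    def nearest_frame(self, time_s: float) -> int:
        i = int(np.searchsorted(self.t, time_s))
        if i == 0:
            return 0
        if i >= len(self.t):
            return len(self.t) - 1
        # tie goes to the earlier frame
        return i - 1 if time_s - self.t[i - 1] <= self.t[i] - time_s else i

    def snout_interp(self, time_s: float) -> np.ndarray:
        return np.array([np.interp(time_s, self.t, self.snout[:, k])
                         for k in (0, 1)])


# ---------------------------------------------------------------------------
# waveforms

def synth_chirp(f_start: float, f_end: float, duration: float,
                sample_rate: float, shape: str = "linear",
                taper_s: float = 1e-3) -> np.ndarray:
    """Unit-peak frequency sweep with raised-cosine onset/offset tapers.

    ``shape`` selects the instantaneous-frequency trajectory: "linear" or
    "logistic" (s-curve dwelling near the endpoint frequencies).
    """
    nyq = sample_rate / 2
    for f in (f_start, f_end):
        if not 0 < f < nyq:
            raise ValueError(f"frequency {f} Hz outside (0, Nyquist)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if shape == "linear":
        finst = f_start + (f_end - f_start) * t / duration
    elif shape == "logistic":
        u = 8.0 * (t / duration - 0.5)
        finst = f_start + (f_end - f_start) / (1.0 + np.exp(-u))
    else:
        raise ValueError(f"unknown sweep shape {shape!r}")
    phase = 2 * np.pi * np.cumsum(finst) / sample_rate
    w = np.sin(phase)
    # raised-cosine taper, at least taper_s but never more than half the call
    nt = max(2, int(round(min(taper_s, duration / 2) * sample_rate)))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nt) / nt))
    w[:nt] *= ramp
    w[-nt:] *= ramp[::-1]
    return w


def fractional_delay_block(waveform: np.ndarray, delays_samples: np.ndarray,
                           gains: np.ndarray) -> np.ndarray:
    """Delay one waveform per channel by fractional sample counts.

    Uses FFT phase shifts (exact for band-limited signals), which matters
    here because inter-channel arrival differences across the overhead
    array are fractions of a sample at 250 kHz.

    Returns an (n_channels, L) block; ``delays_samples`` must be >= 0.
    """
    delays = np.asarray(delays_samples, dtype=float)
    gains = np.asarray(gains, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    L = len(waveform) + int(np.ceil(delays.max())) + 8
    X = rfft(waveform, L)
    f = rfftfreq(L)  # cycles/sample
    phase = np.exp(-2j * np.pi * np.outer(delays, f))
    return gains[:, None] * irfft(X[None, :] * phase, L, axis=1)


def propagate_to_mics(waveform: np.ndarray, source, array: MicArrayGeometry,
                      c: float, sample_rate: float) -> MultiChannelRecording:
    """Forward model: delay + 1/r spherical spreading onto each channel."""
    src = np.asarray(source, dtype=float)
    tau = np.atleast_1d(propagation_delay(src, array.positions, c))
    r = tau * c
    gains = R_REF_MM / r
    block = fractional_delay_block(waveform, tau * sample_rate, gains)
    return MultiChannelRecording(block, sample_rate, label=array.label)


# ---------------------------------------------------------------------------
# sensor noise

def _add_noise_chunked(data: np.ndarray, model: str, sigma: float,
                       sample_rate: float, knee_hz: float,
                       rng: np.random.Generator,
                       chunk: int = 1 << 20) -> None:
    """Add scaled sensor noise into ``data`` chunk-wise (bounded memory).

    The MEMS ("cam64") model is unit-flat noise plus an independent
    differentiated component whose power rises ~6 dB/octave above the knee
    frequency; "usm4" is flat.  The first difference is carried across
    chunk boundaries so the spectrum is seamless.
    """
    n_ch, n = data.shape
    b = np.float32(sample_rate / (2 * np.pi * knee_hz))
    s = np.float32(sigma)
    prev = np.zeros((n_ch, 1), dtype=np.float32)
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        w1 = rng.standard_normal((n_ch, m), dtype=np.float32)
        if model == "cam64":
            w2 = rng.standard_normal((n_ch, m), dtype=np.float32)
            d = np.empty_like(w2)
            d[:, 0] = w2[:, 0] - prev[:, 0]
            np.subtract(w2[:, 1:], w2[:, :-1], out=d[:, 1:])
            prev[:, 0] = w2[:, -1]
            w1 += b * d
        data[:, start:start + m] += s * w1


def _mems_gain_sq(f: np.ndarray, sample_rate: float, knee_hz: float) -> np.ndarray:
    b = sample_rate / (2 * np.pi * knee_hz)
    return 1.0 + (b * 2 * np.sin(np.pi * f / sample_rate)) ** 2


def noise_inband_power(model: str, sample_rate: float,
                       band: tuple[float, float] = (30e3, 110e3),
                       knee_hz: float = 60e3) -> float:
    """Expected in-band power of the unit noise process of ``model``."""
    f = np.linspace(0, sample_rate / 2, 4097)
    psd = np.ones_like(f)
    if model == "cam64":
        psd = _mems_gain_sq(f, sample_rate, knee_hz)
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(psd[mask], f[mask]) / (sample_rate / 2))


def add_sensor_noise(rec: MultiChannelRecording, model: str,
                     band_snr_db: float, rng=None,
                     band: tuple[float, float] = (30e3, 110e3),
                     knee_hz: float = 60e3,
                     signal_power: float | None = None,
                     copy: bool = True) -> MultiChannelRecording:
    """Add technology-specific sensor noise at a requested in-band SNR.

    ``model`` is "cam64" (noise floor rising above ``knee_hz``) or "usm4"
    (flat).  The SNR is defined over ``band`` against ``signal_power``, the
    mean in-band signal power per channel over signal-active samples; when
    not supplied it is measured from the recording itself (samples whose
    smoothed in-band power exceeds 1e-4 of the peak count as active).
    ``band_snr_db = inf`` returns the input unchanged.  ``copy=False``
    mutates the sample matrix in place (bounded memory on long scenes).
    """
    if not np.isfinite(band_snr_db):
        if band_snr_db > 0:
            return rec
        raise ValueError("band_snr_db must be finite or +inf")
    if model not in ("cam64", "usm4"):
        raise ValueError(f"unknown noise model {model!r}")
    rng = np.random.default_rng(rng)
    fs = rec.sample_rate
    if signal_power is None:
        signal_power = measure_active_band_power(rec.data, fs, band)
    target_noise_power = signal_power * 10 ** (-band_snr_db / 10)
    unit_power = noise_inband_power(model, fs, band, knee_hz)
    sigma = np.sqrt(target_noise_power / unit_power)
    data = rec.data if not copy else rec.data.copy()
    _add_noise_chunked(data, model, sigma, fs, knee_hz, rng)
    return replace(rec, data=data)


def measure_active_band_power(data: np.ndarray, fs: float,
                              band: tuple[float, float],
                              rel_floor: float = 1e-4) -> float:
    """Mean in-band power per channel over signal-active samples."""
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import sosfilt, butter
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, np.asarray(data, dtype=np.float64), axis=-1)
    p = (x ** 2).mean(axis=0)
    p = uniform_filter1d(p, max(3, int(round(2.5e-3 * fs))))
    active = p > rel_floor * p.max()
    if not active.any():
        raise ValueError("recording contains no signal to reference SNR to")
    return float(p[active].mean())


# ---------------------------------------------------------------------------
# pose tracks

def _smooth_walk(n: int, rng: np.random.Generator, step: float,
                 smooth_frames: float = 8.0) -> np.ndarray:
    w = rng.standard_normal(n) * step
    return gaussian_filter1d(np.cumsum(w), smooth_frames, mode="nearest")


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (triangle-wave folding, keeps smoothness)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def gen_tracks(n_mice: int, duration: float, frame_rate: float = 55.6,
               profile: str = "close", seed=None,
               scene: SceneConfig | None = None,
               sexes: list[str] | None = None) -> list[MouseTrack]:
    """Smooth bounded random-walk pose tracks on the platform.

    ``profile`` shapes the snout-snout distance distribution:

    - "close": partner mice orbit the focal mouse at ~40 mm, emulating the
      close-contact structure of courtship interactions (most frames within
      10 cm snout-snout distance);
    - "far": partners kept around 170 mm away (low-confusion regime);
    - "free": independent walks.
    """
    if n_mice not in (1, 2, 3):
        raise ValueError("n_mice must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    scene = scene or default_scene()
    x0, x1, y0, y1 = scene.platform.bounds
    m = 25.0  # keep body centres this far from the edge
    bx = (x0 + m, x1 - m)
    by = (y0 + m, y1 - m)
    F = max(2, int(round(duration * frame_rate)) + 1)
    t = np.arange(F) / frame_rate
    if sexes is None:
        sexes = (["female"] + ["male"] * (n_mice - 1)) if n_mice > 1 else ["male"]

    # close profile: keep the focal walk away from the edges so partner
    # positions rarely need boundary folding (which would break the
    # intended snout-snout distance distribution)
    radius = {"close": (40.0, 18.0, 18.0, 85.0),
              "far": (170.0, 25.0, 120.0, 240.0),
              "free": None}[profile]
    shrink = 50.0 if profile == "close" and n_mice > 1 else 0.0
    bbx = (bx[0] + shrink, bx[1] - shrink)
    bby = (by[0] + shrink, by[1] - shrink)
    centers = []
    base = np.column_stack([
        _fold(rng.uniform(*bbx) + _smooth_walk(F, rng, 12.0), *bbx),
        _fold(rng.uniform(*bby) + _smooth_walk(F, rng, 12.0), *bby),
    ])
    centers.append(base)
    for i in range(1, n_mice):
        if profile == "free":
            ci = np.column_stack([
                _fold(rng.uniform(*bx) + _smooth_walk(F, rng, 12.0), *bx),
                _fold(rng.uniform(*by) + _smooth_walk(F, rng, 12.0), *by),
            ])
        else:
            r_mean, r_sd, r_min, r_cap = radius
            r = np.clip(r_mean + _smooth_walk(F, rng, r_sd / 4), r_min, r_cap)
            th = rng.uniform(0, 2 * np.pi) + _smooth_walk(F, rng, 0.15) \
                + (0 if n_mice == 2 else 2 * np.pi * i / n_mice)
            ci = base + np.column_stack([r * np.cos(th), r * np.sin(th)])
            ci[:, 0] = _fold(ci[:, 0], *bx)
            ci[:, 1] = _fold(ci[:, 1], *by)
        centers.append(ci)

    tracks = []
    for i, ci in enumerate(centers):
        phi = rng.uniform(0, 2 * np.pi) + _smooth_walk(F, rng, 0.25)
        gaze = np.column_stack([np.cos(phi), np.sin(phi)])
        tracks.append(MouseTrack(
            mouse_id=i, sex=sexes[i], t=t,
            snout=ci + HALF_BODY_MM * gaze,
            head_center=ci - HALF_BODY_MM * gaze,
        ))
    return tracks


def snout_distances(tracks: list[MouseTrack]) -> np.ndarray:
    """(F,) minimum pairwise snout-snout distance per frame (inf if 1 mouse)."""
    F = len(tracks[0].t)
    if len(tracks) < 2:
        return np.full(F, np.inf)
    d = np.full(F, np.inf)
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            dij = np.linalg.norm(tracks[i].snout - tracks[j].snout, axis=1)
            d = np.minimum(d, dij)
    return d


# ---------------------------------------------------------------------------
# vocalization schedule and full-scene rendering

def make_usv_schedule(tracks: list[MouseTrack], n_usvs: int,
                      t_range: tuple[float, float], seed=None,
                      f_band: tuple[float, float] = (50e3, 80e3),
                      dur_range: tuple[float, float] = (40e-3, 60e-3),
                      min_gap: float = 0.1,
                      emitter_weights=None,
                      vhf_fraction: float = 0.0,
                      z_source: float = 10.0) -> list[UsvGroundTruth]:
    """Schedule of chirps emitted from the tracked snout positions.

    Defaults emulate the common repertoire (50-80 kHz sweeps, 40-60 ms).
    ``vhf_fraction`` routes that fraction of calls into a very-high-frequency
    subclass (90-110 kHz) that stresses the MEMS array's rising noise floor.
    """
    rng = np.random.default_rng(seed)
    if n_usvs == 0:
        return []
    t0, t1 = t_range
    slot = (t1 - t0) / n_usvs
    if slot < dur_range[1] + min_gap:
        raise ValueError("schedule too dense for the requested time range")
    weights = np.asarray(emitter_weights if emitter_weights is not None
                         else np.ones(len(tracks)), dtype=float)
    weights = weights / weights.sum()
    events = []
    for k in range(n_usvs):
        dur = rng.uniform(*dur_range)
        onset = t0 + k * slot + rng.uniform(0, slot - dur - min_gap)
        emitter = rng.choice(len(tracks), p=weights)
        if rng.uniform() < vhf_fraction:
            lo, hi = 90e3, 110e3
        else:
            lo, hi = f_band
        fa, fb = np.sort(rng.uniform(lo, hi, 2))
        while fb - fa < 5e3:  # keep an audible sweep extent
            fa, fb = np.sort(rng.uniform(lo, hi, 2))
        if rng.uniform() < 0.5:
            fa, fb = fb, fa
        src = tracks[emitter].snout_interp(onset + dur / 2)
        events.append(UsvGroundTruth(
            onset=onset, offset=onset + dur,
            source=np.array([src[0], src[1], z_source]),
            emitter_id=int(emitter), f_start=float(fa), f_end=float(fb),
            amplitude=float(rng.lognormal(0.0, 0.15)),
        ))
    for a, b in zip(events, events[1:]):
        if b.onset < a.offset:
            a.overlaps = b.overlaps = True
    return events


@dataclass
class SceneBundle:
    """Everything produced by rendering one synthetic scene."""

    scene: SceneConfig
    recordings: dict[str, MultiChannelRecording]
    tracks: list[MouseTrack]
    ground_truth: list[UsvGroundTruth]
    click_times: dict[str, tuple[float, float]]   # per stream, local clocks
    params: dict = field(default_factory=dict)


def _add_block(dest: np.ndarray, block: np.ndarray, n0: int) -> None:
    L = block.shape[1]
    lo = max(0, n0)
    hi = min(dest.shape[1], n0 + L)
    if hi > lo:
        dest[:, lo:hi] += block[:, lo - n0:hi - n0].astype(dest.dtype)


def _place_event(dest: np.ndarray, waveform: np.ndarray, gains: np.ndarray,
                 t_arrival_local: np.ndarray, fs: float) -> None:
    n0 = int(np.floor(t_arrival_local.min() * fs)) - 4
    delays = t_arrival_local * fs - n0
    _add_block(dest, fractional_delay_block(waveform, delays, gains), n0)


def render_scene(tracks: list[MouseTrack],
                 schedule: list[UsvGroundTruth],
                 scene: SceneConfig | None = None,
                 cam64_snr_db: float = 10.0,
                 usm4_snr_db: float = 10.0,
                 seed=None,
                 clock_offset: float = 0.012,
                 clock_drift: float = 1.00002,
                 duration: float | None = None,
                 click_amplitude: float = 20.0) -> SceneBundle:
    """Render both microphone sets for one scene.

    The two recorders run on independent clocks related by
    ``t_usm4 = clock_offset + clock_drift * t_cam64``; two broadband
    synchronization clicks are inserted near the start and end of the trial
    on both streams.  Sensor noise is added per array model at the requested
    in-band SNR (referenced to the mean vocalization power; ``inf`` disables
    noise).  Ground-truth sources are the emitting mice's snout positions.
    """
    scene = scene or default_scene()
    rng = np.random.default_rng(seed)
    fs = scene.sample_rate
    c = scene.speed_of_sound
    if duration is None:
        duration = (max(ev.offset for ev in schedule) + 0.2) if schedule \
            else tracks[0].t[-1]
    for ev in schedule:
        if ev.onset < 0 or ev.offset > duration:
            raise ValueError("schedule event outside scene duration")
    for a, b in zip(sorted(schedule, key=lambda e: e.onset),
                    sorted(schedule, key=lambda e: e.onset)[1:]):
        if b.onset < a.offset:       # overlaps allowed, but flagged
            a.overlaps = b.overlaps = True

    n_usm = int(round(duration * fs))
    t_cam_end = (duration - clock_offset) / clock_drift
    n_cam = int(round(t_cam_end * fs))
    data = {"usm4": np.zeros((4, n_usm), dtype=np.float32),
            "cam64": np.zeros((64, n_cam), dtype=np.float32)}

    def to_cam(t_usm):
        return (t_usm - clock_offset) / clock_drift

    sig_power = {"usm4": [], "cam64": []}
    for ev in schedule:
        w = ev.amplitude * synth_chirp(ev.f_start, ev.f_end,
                                       ev.offset - ev.onset, fs)
        p_wave = float(np.mean(w ** 2))
        for name in ("usm4", "cam64"):
            arr = scene.arrays[name]
            tau = np.atleast_1d(propagation_delay(ev.source, arr.positions, c))
            gains = R_REF_MM / (tau * c)
            t_arr = ev.onset + tau
            if name == "cam64":
                t_arr = to_cam(t_arr)
            _place_event(data[name], w, gains, t_arr, fs)
            sig_power[name].append(p_wave * float(np.mean(gains ** 2)))

    # synchronization clicks: identical broadband transient on all channels
    click_usm = (0.05, duration - 0.05)
    click_wave = click_amplitude * synth_chirp(30e3, 110e3, 0.8e-3, fs,
                                               taper_s=0.2e-3)
    for name in ("usm4", "cam64"):
        for t_click in click_usm:
            t_local = t_click if name == "usm4" else to_cam(t_click)
            n0 = int(round(t_local * fs))
            _add_block(data[name], click_wave[None, :].repeat(
                data[name].shape[0], axis=0), n0)

    recs = {}
    for name in ("usm4", "cam64"):
        rec = MultiChannelRecording(data[name], fs, label=name)
        snr = usm4_snr_db if name == "usm4" else cam64_snr_db
        if schedule and np.isfinite(snr):
            rec = add_sensor_noise(
                rec, name, snr, rng=rng,
                signal_power=float(np.mean(sig_power[name])), copy=False)
        recs[name] = rec

    clicks = {"usm4": click_usm,
              "cam64": (to_cam(click_usm[0]), to_cam(click_usm[1]))}
    return SceneBundle(
        scene=scene, recordings=recs, tracks=tracks, ground_truth=schedule,
        click_times=clicks,
        params={"cam64_snr_db": cam64_snr_db, "usm4_snr_db": usm4_snr_db,
                "clock_offset": clock_offset, "clock_drift": clock_drift,
                "duration": duration, "seed": seed},
    )
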