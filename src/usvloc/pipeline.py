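"""End-to-end pipeline: simulate -> detect -> localize -> assign -> evaluate.

These functions tie the modules together exactly the way the command-line
driver does, and are reused directly by the acceptance experiments.
"""

from __future__ import annotations

import numpy as np

from . import assign as assign_mod
from .assign import (MOUTH_FRACTION_MANUAL, assign_dataset,
                     min_snout_distance_at, summarize_assignments)
from .beamform import localize_cam64
from .geometry import SceneConfig, default_scene
from .preprocess import (ClockMap, align_clocks, bandpass_usm4, detect_clicks,
                         detect_usvs, match_segments, UsvSegment)
from .slim import SlimLocalizer
from .synth import (SceneBundle, gen_tracks, make_usv_schedule, propagate_to_mics,
                    render_scene, synth_chirp)

SCHEDULE_MARGIN_S = 0.3


def simulate(profile: str = "close", n_mice: int = 2, n_usvs: int = 200,
             cam64_snr_db: float = 10.0, usm4_snr_db: float = 10.0,
             seed: int = 0, scene: SceneConfig | None = None,
             usv_slot_s: float = 0.18,
             f_band: tuple[float, float] = (50e3, 80e3),
             dur_range: tuple[float, float] = (40e-3, 60e-3),
             vhf_fraction: float = 0.0,
             emitter_weights=None) -> SceneBundle:
    """Simulate one recording trial with ground truth.

    Calls are scheduled at roughly one per ``usv_slot_s`` within the trial,
    leaving a margin around the synchronization clicks.
    """
    scene = scene or default_scene()
    duration = n_usvs * usv_slot_s + 2 * SCHEDULE_MARGIN_S
    tracks = gen_tracks(n_mice, duration, profile=profile, seed=seed,
                        scene=scene)
    schedule = make_usv_schedule(
        tracks, n_usvs, (SCHEDULE_MARGIN_S, duration - SCHEDULE_MARGIN_S),
        seed=seed + 1, f_band=f_band, dur_range=dur_range,
        vhf_fraction=vhf_fraction, emitter_weights=emitter_weights,
        z_source=scene.platform.z_plane)
    return render_scene(tracks, schedule, scene, cam64_snr_db=cam64_snr_db,
                        usm4_snr_db=usm4_snr_db, seed=seed + 2,
                        duration=duration)


def recover_clock_map(bundle: SceneBundle,
                      search_s: float = 0.2) -> ClockMap:
    """Clock map usm4 -> cam64 recovered from the synchronization clicks."""
    cu = detect_clicks(bundle.recordings["usm4"], search_s=search_s)
    cc = detect_clicks(bundle.recordings["cam64"], search_s=search_s)
    return align_clocks(cu, cc)


def detect(bundle: SceneBundle, **kw) -> list:
    """Band-pass the peripheral channels and detect calls on them."""
    filtered = bandpass_usm4(bundle.recordings["usm4"])
    return detect_usvs(filtered, **kw)


def localize(bundle: SceneBundle, segments: list,
             methods=("cam64", "slim"), clock_map: ClockMap | None = None,
             max_freqs: int = 64) -> dict[str, list]:
    """Per-call localization estimates for the requested methods."""
    out: dict[str, list] = {m: [None] * len(segments) for m in methods}
    if clock_map is None and "cam64" in methods:
        clock_map = recover_clock_map(bundle)
    slim = SlimLocalizer(bundle.scene) if "slim" in methods else None
    for k, seg in enumerate(segments):
        if "cam64" in methods:
            out["cam64"][k] = localize_cam64(
                seg, bundle.recordings["cam64"], bundle.scene,
                clock_map=clock_map, max_freqs=max_freqs)
        if "slim" in methods:
            out["slim"][k] = slim.localize(seg, bundle.recordings["usm4"])
    return out


def run(bundle: SceneBundle, methods=("cam64", "slim"),
        strategy: str = "hybrid", snr_gate: float | None = None,
        mouth_fraction: float = MOUTH_FRACTION_MANUAL,
        max_freqs: int = 64, detect_kw: dict | None = None) -> dict:
    """Full pipeline on one bundle; returns all intermediate products."""
    segments = detect(bundle, **(detect_kw or {}))
    estimates = localize(bundle, segments, methods=methods,
                         max_freqs=max_freqs)
    cam = estimates.get("cam64", [None] * len(segments))
    slm = estimates.get("slim", [None] * len(segments))
    results = assign_dataset(segments, cam, slm, bundle.tracks,
                             mouth_fraction=mouth_fraction,
                             strategy=strategy, snr_gate=snr_gate)
    seg2truth = match_segments(segments, bundle.ground_truth)
    summary = summarize_assignments(results, bundle.ground_truth, seg2truth)
    return {"segments": segments, "estimates": estimates,
            "assignments": results, "segment_to_truth": seg2truth,
            "summary": summary}


def evaluate(bundle: SceneBundle, out: dict) -> dict:
    """Accuracy metrics of a pipeline run against the bundle ground truth.

    Errors are Euclidean distances between assigned origins and the true
    source positions; the far condition keeps calls whose minimum pairwise
    snout distance at the call midpoint exceeds 100 mm.
    """
    segs = out["segments"]
    seg2truth = out["segment_to_truth"]
    errors, far, assigned_mask = [], [], []
    far_detected = 0
    for k, seg in enumerate(segs):
        ti = seg2truth[k]
        if ti is None:
            continue
        ev = bundle.ground_truth[ti]
        is_far = min_snout_distance_at(bundle.tracks, ev.midpoint) > \
            assign_mod.FAR_CONDITION_MM
        far_detected += int(is_far)
        r = out["assignments"][k]
        if r.assigned:
            errors.append(float(np.linalg.norm(r.origin - ev.source[:2])))
            far.append(is_far)
            assigned_mask.append(k)
    errors = np.asarray(errors)
    far = np.asarray(far, dtype=bool)
    res = {
        "n_detected": len(segs),
        "n_assigned": int(len(errors)),
        "assigned_fraction": len(errors) / len(segs) if segs else np.nan,
        "mae_mm": float(np.median(errors)) if len(errors) else np.nan,
        "n_far_detected": far_detected,
        "n_far_assigned": int(far.sum()),
        "far_assigned_fraction": float(far.sum() / far_detected)
        if far_detected else np.nan,
        "mae_far_mm": float(np.median(errors[far])) if far.any() else np.nan,
    }
    return res


# ---------------------------------------------------------------------------
# static-source (speaker-style) calibration experiment

def speaker_grid_errors(scene: SceneConfig | None = None,
                        nx: int = 5, ny: int = 5,
                        f_start: float = 50e3, f_end: float = 80e3,
                        duration: float = 50e-3,
                        margin_mm: float = 40.0,
                        max_freqs: int = 64) -> np.ndarray:
    """Localization errors for noise-free static sources on a regular grid.

    Emulates a miniature-speaker calibration: one chirp per position on an
    ``nx x ny`` grid spanning the platform, rendered without sensor noise,
    localized with the two-step beamforming scan.  Returns the (nx*ny,)
    absolute 2D errors in mm.
    """
    scene = scene or default_scene()
    x0, x1, y0, y1 = scene.platform.bounds
    xs = np.linspace(x0 + margin_mm, x1 - margin_mm, nx)
    ys = np.linspace(y0 + margin_mm, y1 - margin_mm, ny)
    fs = scene.sample_rate
    wave = synth_chirp(f_start, f_end, duration, fs)
    errors = []
    for x in xs:
        for y in ys:
            src = np.array([x, y, scene.platform.z_plane])
            rec = propagate_to_mics(wave, src, scene.cam64,
                                    scene.speed_of_sound, fs)
            seg = UsvSegment(onset=0.0, offset=rec.duration,
                             f_lo=min(f_start, f_end) - 5e3,
                             f_hi=max(f_start, f_end) + 5e3)
            est = localize_cam64(seg, rec, scene, max_freqs=max_freqs)
            errors.append(np.linalg.norm(est.origin - src[:2]))
    return np.asarray(errors)
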