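"""Standard simulation benchmarks for the localization pipeline.

Each benchmark renders ground-truthed synthetic trials under the reference
recording conditions (default geometry, 10 dB in-band sensor SNR, 50-80 kHz
calls of 40-60 ms), runs the full pipeline, and reports median absolute
localization errors and assignment rates.  Datasets are built from several
moderate-length trials (like the multi-trial structure of real experiments),
which also bounds the memory footprint of the 64-channel renders; results
are pooled across trials before taking medians.
"""

from __future__ import annotations

import numpy as np

from . import pipeline
from .assign import assign_dataset

TRIAL_USVS = 100


def _trial_seeds(seed: int, n_trials: int) -> list[int]:
    return [int(seed + 7919 * k) for k in range(n_trials)]


def _errors_for(results, seg2truth, bundle):
    errs = []
    for r in results:
        ti = seg2truth[r.usv_index]
        if r.assigned and ti is not None:
            ev = bundle.ground_truth[ti]
            errs.append(float(np.linalg.norm(r.origin - ev.source[:2])))
    return errs


def _run_trials(seed, n_usvs, snr_db, profile, n_mice, process):
    """Render/analyze one trial at a time; only ``process(bundle, out)``
    results are retained (a 64-channel render is large, so at most one
    trial's audio lives in memory)."""
    n_trials = max(1, int(np.ceil(n_usvs / TRIAL_USVS)))
    per_trial = int(np.ceil(n_usvs / n_trials))
    collected = []
    for s in _trial_seeds(seed, n_trials):
        bundle = pipeline.simulate(profile=profile, n_mice=n_mice,
                                   n_usvs=per_trial, cam64_snr_db=snr_db,
                                   usm4_snr_db=snr_db, seed=s)
        out = pipeline.run(bundle)
        collected.append(process(bundle, out))
        del bundle, out
    return collected


def dyadic_benchmark(seed: int, n_usvs: int = 200,
                     snr_db: float = 10.0) -> dict:
    """Dyadic close-contact trials: hybrid and single-method accuracies.

    Reports the hybrid median absolute error over assigned calls, plus the
    per-method errors over each method's own reliably-assignable subset
    (assignment re-run with the other method's estimates withheld).
    """
    def process(bundle, out):
        segs, s2t = out["segments"], out["segment_to_truth"]
        n = len(segs)
        trial = {"n": n}
        for method in ("hybrid", "cam64", "slim"):
            if method == "hybrid":
                results = out["assignments"]
            else:
                cam = out["estimates"]["cam64"] if method == "cam64" \
                    else [None] * n
                slm = out["estimates"]["slim"] if method == "slim" \
                    else [None] * n
                results = assign_dataset(segs, cam, slm, bundle.tracks)
            trial[method] = (_errors_for(results, s2t, bundle),
                             sum(r.assigned for r in results))
        return trial

    trials = _run_trials(seed, n_usvs, snr_db, "close", 2, process)
    n_detected = sum(t["n"] for t in trials)
    res = {"n_usvs": n_usvs, "n_detected": n_detected}
    for method in ("hybrid", "cam64", "slim"):
        errs = sum((t[method][0] for t in trials), [])
        res[f"{method}_mae_mm"] = float(np.median(errs)) if errs else np.nan
        res[f"{method}_assigned_pct"] = 100 * sum(
            t[method][1] for t in trials) / n_detected
    return res


def far_benchmark(seed: int, n_usvs: int = 200,
                  snr_db: float = 10.0) -> dict:
    """Wide-separation trials: accuracy and assignment in the far condition
    (calls emitted while all snouts are >100 mm apart)."""
    from .assign import FAR_CONDITION_MM, min_snout_distance_at

    def process(bundle, out):
        ev = pipeline.evaluate(bundle, out)
        errs = []
        s2t = out["segment_to_truth"]
        for r in out["assignments"]:
            ti = s2t[r.usv_index]
            if not r.assigned or ti is None:
                continue
            gt = bundle.ground_truth[ti]
            if min_snout_distance_at(bundle.tracks,
                                     gt.midpoint) > FAR_CONDITION_MM:
                errs.append(float(np.linalg.norm(r.origin - gt.source[:2])))
        return {"errs": errs, "n_far": ev["n_far_detected"],
                "n_far_assigned": ev["n_far_assigned"]}

    trials = _run_trials(seed, n_usvs, snr_db, "far", 2, process)
    errs = sum((t["errs"] for t in trials), [])
    n_far = sum(t["n_far"] for t in trials)
    n_far_assigned = sum(t["n_far_assigned"] for t in trials)
    return {"far_mae_mm": float(np.median(errs)) if errs else np.nan,
            "far_assigned_pct": 100 * n_far_assigned / n_far if n_far
            else np.nan,
            "n_far": n_far, "n_usvs": n_usvs}


def single_mouse_benchmark(seed: int, n_usvs: int = 200,
                           snr_db: float = 10.0) -> dict:
    """Single-animal trials: one mouse emits every call."""
    def process(bundle, out):
        return {"errs": _errors_for(out["assignments"],
                                    out["segment_to_truth"], bundle),
                "n": len(out["segments"]),
                "n_assigned": sum(r.assigned for r in out["assignments"])}

    trials = _run_trials(seed, n_usvs, snr_db, "free", 1, process)
    errs = sum((t["errs"] for t in trials), [])
    n_detected = sum(t["n"] for t in trials)
    return {"single_mae_mm": float(np.median(errs)) if errs else np.nan,
            "single_assigned_pct": 100 * sum(t["n_assigned"]
                                             for t in trials) / n_detected,
            "n_usvs": n_usvs}


def speaker_benchmark(nx: int = 5, ny: int = 5) -> dict:
    """Noise-free static-source grid (miniature-speaker style calibration)."""
    errs = pipeline.speaker_grid_errors(nx=nx, ny=ny)
    return {"speaker_mae_mm": float(np.median(errs)), "n_sources": nx * ny}
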