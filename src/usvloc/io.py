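"""File IO: multichannel WAV, track CSV, ground-truth and summary JSON.

A rendered scene is persisted as a bundle directory:

    scene.json          scene geometry + sample rate
    cam64.wav, usm4.wav 16-bit PCM multichannel audio
    tracks.csv          frame, time_s, mouse_id, sex, snout/head coordinates
    ground_truth.json   scheduled calls with true origins (when synthetic)
    bundle.json         provenance (seed, config hash), clock/click metadata,
                        per-file amplitude scales (WAV is integer-quantized)

Stage outputs (segments, estimates, assignments) are plain CSV tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .beamform import LocalizationEstimate
from .geometry import SceneConfig
from .preprocess import UsvSegment
from .recording import MultiChannelRecording
from .synth import MouseTrack, SceneBundle, UsvGroundTruth

_I16_MAX = 32767


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# WAV

def write_wav(path, rec: MultiChannelRecording,
              headroom: float = 0.5) -> float:
    """Write a recording as 16-bit PCM WAV; returns the amplitude scale.

    Samples are scaled so the peak sits at ``headroom`` of full scale;
    multiply the ints by ``scale / 32767`` to recover the original floats.
    """
    peak = float(np.abs(rec.data).max())
    scale = peak / headroom if peak > 0 else 1.0
    q = np.clip(rec.data / scale * _I16_MAX, -_I16_MAX, _I16_MAX)
    wavfile.write(path, int(rec.sample_rate), q.astype(np.int16).T.copy())
    return scale


def read_wav(path, label: str = "", scale: float = 1.0,
             mmap: bool = False) -> MultiChannelRecording:
    fs, data = wavfile.read(path, mmap=mmap)
    if data.ndim == 1:
        data = data[:, None]
    out = data.T.astype(np.float32) * np.float32(scale / _I16_MAX)
    return MultiChannelRecording(out, float(fs), label=label)


# ---------------------------------------------------------------------------
# tracks

def tracks_to_csv(path, tracks: list[MouseTrack], units: str = "mm") -> None:
    rows = []
    for tr in tracks:
        for k in range(len(tr.t)):
            rows.append({
                "frame": k, "time_s": tr.t[k], "mouse_id": tr.mouse_id,
                "sex": tr.sex,
                "snout_x_mm": tr.snout[k, 0], "snout_y_mm": tr.snout[k, 1],
                "head_x_mm": tr.head_center[k, 0],
                "head_y_mm": tr.head_center[k, 1],
            })
    df = pd.DataFrame(rows)
    df.attrs["units"] = units
    df.to_csv(path, index=False)


def tracks_from_csv(path) -> list[MouseTrack]:
    df = pd.read_csv(path)
    tracks = []
    for mid, g in df.groupby("mouse_id"):
        g = g.sort_values("frame")
        tracks.append(MouseTrack(
            mouse_id=int(mid), sex=str(g["sex"].iloc[0]),
            t=g["time_s"].to_numpy(),
            snout=g[["snout_x_mm", "snout_y_mm"]].to_numpy(),
            head_center=g[["head_x_mm", "head_y_mm"]].to_numpy(),
        ))
    return tracks


# ---------------------------------------------------------------------------
# bundles

def save_bundle(outdir, bundle: SceneBundle, seed=None) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.scene.save(out / "scene.json")
    scales = {}
    for name, rec in bundle.recordings.items():
        scales[name] = write_wav(out / f"{name}.wav", rec)
    tracks_to_csv(out / "tracks.csv", bundle.tracks)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump([ev.to_dict() for ev in bundle.ground_truth], fh, indent=1)
    meta = {
        "seed": seed if seed is not None else bundle.params.get("seed"),
        "params": {k: v for k, v in bundle.params.items() if k != "seed"},
        "click_times": {k: list(v) for k, v in bundle.click_times.items()},
        "wav_scales": scales,
    }
    meta["config_hash"] = config_hash(
        {"scene": bundle.scene.to_dict(), "params": meta["params"],
         "seed": meta["seed"]})
    with open(out / "bundle.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out


def load_bundle(indir) -> SceneBundle:
    ind = Path(indir)
    scene = SceneConfig.load(ind / "scene.json")
    with open(ind / "bundle.json") as fh:
        meta = json.load(fh)
    recordings = {
        name: read_wav(ind / f"{name}.wav", label=name, scale=scale)
        for name, scale in meta["wav_scales"].items()
    }
    with open(ind / "ground_truth.json") as fh:
        gt = [UsvGroundTruth.from_dict(d) for d in json.load(fh)]
    params = dict(meta.get("params", {}))
    params["seed"] = meta.get("seed")
    return SceneBundle(
        scene=scene, recordings=recordings,
        tracks=tracks_from_csv(ind / "tracks.csv"), ground_truth=gt,
        click_times={k: tuple(v) for k, v in meta["click_times"].items()},
        params=params,
    )


# ---------------------------------------------------------------------------
# stage tables

def segments_to_csv(path, segments: list[UsvSegment]) -> None:
    pd.DataFrame([{
        "usv_id": k, "onset_s": s.onset, "offset_s": s.offset,
        "f_lo_hz": s.f_lo, "f_hi_hz": s.f_hi, "energy": s.energy,
    } for k, s in enumerate(segments)]).to_csv(path, index=False)


def segments_from_csv(path) -> list[UsvSegment]:
    df = pd.read_csv(path)
    return [UsvSegment(onset=r.onset_s, offset=r.offset_s, f_lo=r.f_lo_hz,
                       f_hi=r.f_hi_hz, energy=r.energy)
            for r in df.itertuples()]


def estimates_to_csv(path, estimates: dict[str, list]) -> None:
    rows = []
    for method, lst in estimates.items():
        for k, e in enumerate(lst):
            if e is None:
                rows.append({"usv_id": k, "method": method, "x_mm": np.nan,
                             "y_mm": np.nan, "uncertainty": np.nan,
                             "snr": np.nan})
            else:
                rows.append({"usv_id": k, "method": method,
                             "x_mm": e.origin[0], "y_mm": e.origin[1],
                             "uncertainty": e.uncertainty,
                             "snr": e.snr if e.snr is not None else np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


def estimates_from_csv(path) -> dict[str, list]:
    df = pd.read_csv(path)
    out: dict[str, list] = {}
    for method, g in df.groupby("method"):
        g = g.sort_values("usv_id")
        lst = []
        for r in g.itertuples():
            if np.isnan(r.x_mm):
                lst.append(None)
            else:
                lst.append(LocalizationEstimate(
                    origin=np.array([r.x_mm, r.y_mm]),
                    uncertainty=r.uncertainty, method=method,
                    snr=None if np.isnan(r.snr) else r.snr))
        out[method] = lst
    return out


def assignments_to_csv(path, results) -> None:
    rows = []
    for r in results:
        mpis = {f"mpi_{m}": float(v.max())
                for m, v in r.mpi_per_method.items()}
        rows.append({
            "usv_id": r.usv_index, "method": r.method,
            "mouse_id": r.mouse_id if r.assigned else -1,
            "residual_mm": r.residual_mm,
            "x_mm": r.origin[0] if r.origin is not None else np.nan,
            "y_mm": r.origin[1] if r.origin is not None else np.nan,
            "reason": r.reason or "", **mpis,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
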