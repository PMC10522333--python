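"""Emitter assignment: Mouse Probability Index and hybrid method fusion.

Each localization method (overhead-array beamforming, four-microphone TDOA)
produces per-call origin estimates with an intrinsic uncertainty.  For each
candidate mouse k the Mouse Probability Index is

    MPI_k = P_k / sum_m P_m,     P_k = N(origin - mouth_k; sigma_method^2)

an isotropic 2D Gaussian likelihood of the mouse's mouth position given the
estimate, normalized across mice.  Mice farther than 50 mm from the estimate
have P_k set to zero (guards against confidently normalizing between
uniformly implausible candidates).  Because the intrinsic uncertainties only
correlate with millimetre error, they are rescaled so that their mean
matches each method's median residual in the far condition (all animals
>100 mm apart), where the nearest mouse is essentially always the emitter.

Fusion: per call, each method's top MPI is checked against 0.95.  If exactly
one method is reliable, it is selected; if both are, the one whose estimate
lies closer to its top mouse wins (ties prefer the beamformer); otherwise
the call stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beamform import LocalizationEstimate
from .preprocess import UsvSegment
from .synth import MouseTrack

MPI_THRESHOLD = 0.95
DISTANCE_GATE_MM = 50.0
FAR_CONDITION_MM = 100.0

#: Mouth offset along the snout->head-centre line: manual-style tracks place
#: the marker on the snout tip (mouth slightly toward the head); automatic
#: trackers place it further back (mouth ahead of the marker).
MOUTH_FRACTION_MANUAL = 0.02
MOUTH_FRACTION_AUTO = -0.15


def mouth_point(snout, head_center, fraction: float = MOUTH_FRACTION_MANUAL):
    """Mouth position on the snout->head-centre line.

    ``fraction`` is signed: positive toward the head centre, negative ahead
    of the snout.
    """
    snout = np.asarray(snout, dtype=float)
    head = np.asarray(head_center, dtype=float)
    if np.allclose(snout, head):
        raise ValueError("snout and head-centre markers coincide")
    return snout + fraction * (head - snout)


def mpi(origin, mouths, sigma_mm: float,
        gate_mm: float = DISTANCE_GATE_MM) -> np.ndarray:
    """Mouse Probability Index for each candidate mouth position.

    Returns an array summing to 1 over in-range mice, or all zeros when
    every mouse is beyond the distance gate.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    mouths = np.atleast_2d(np.asarray(mouths, dtype=float))
    if len(mouths) == 0:
        raise ValueError("need at least one candidate mouse")
    d2 = ((mouths - np.asarray(origin, dtype=float)) ** 2).sum(axis=1)
    in_range = d2 <= gate_mm**2
    if not in_range.any():
        return np.zeros(len(mouths))
    # shift in the log domain: MPI depends only on likelihood ratios, and
    # the shift keeps small sigmas from underflowing every P_k to zero
    log_p = -0.5 * d2 / sigma_mm**2
    p = np.exp(log_p - log_p[in_range].max())
    p[~in_range] = 0.0
    return p / p.sum()


@dataclass(frozen=True)
class CalibrationScale:
    """Multiplicative scales mapping raw per-method uncertainties to mm."""

    scales: dict[str, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("calibration scales must be positive")

    def sigma(self, method: str, raw_uncertainty: float,
              floor_mm: float = 1.0) -> float:
        return max(floor_mm, self.scales[method] * raw_uncertainty)


def calibrate_sigma(raw_uncertainties, far_residuals) -> float:
    """Scale such that the mean scaled uncertainty over all calls equals the
    mean far-condition residual error."""
    raw = np.asarray(raw_uncertainties, dtype=float)
    far = np.asarray(far_residuals, dtype=float)
    if raw.size == 0 or far.size == 0:
        raise ValueError("need non-empty uncertainty and residual lists")
    mraw = raw.mean()
    if mraw <= 0:
        raise ValueError("raw uncertainties have zero mean")
    return float(np.abs(far).mean() / mraw)


@dataclass
class AssignmentResult:
    """Per-call assignment outcome."""

    usv_index: int
    mpi_per_method: dict[str, np.ndarray] = field(default_factory=dict)
    method: str = "none"                   # "cam64" | "slim" | "none"
    mouse_id: int | None = None
    residual_mm: float = np.nan            # distance to the assigned mouth
    origin: np.ndarray | None = None
    reason: str | None = None              # why unassigned

    @property
    def assigned(self) -> bool:
        return self.mouse_id is not None


def hybrid_select(usv_index: int,
                  estimates: dict[str, LocalizationEstimate],
                  mouths: np.ndarray,
                  sigmas: dict[str, float],
                  threshold: float = MPI_THRESHOLD,
                  gate_mm: float = DISTANCE_GATE_MM,
                  snr_gate: float | None = None,
                  strategy: str = "hybrid") -> AssignmentResult:
    """Select a method and mouse for one call.

    ``estimates``/``sigmas`` map method name -> estimate / calibrated sigma.
    ``snr_gate``: optional pre-gate taking the beamformer whenever its field
    SNR exceeds the gate (off by default).  ``strategy`` selects the fusion
    rule: "hybrid" (reliability then smallest residual), or the alternatives
    "mpi" (largest top MPI wins) and "likelihood" (inverse-variance-weighted
    combination of the two origins) for comparison experiments.
    """
    res = AssignmentResult(usv_index=usv_index)
    avail = {m: e for m, e in estimates.items() if e is not None}
    if not avail:
        res.reason = "no-estimate"
        return res
    mouths = np.atleast_2d(mouths)

    info = {}
    for m, est in avail.items():
        v = mpi(est.origin, mouths, sigmas[m], gate_mm)
        res.mpi_per_method[m] = v
        top = int(np.argmax(v))
        dist = float(np.linalg.norm(est.origin - mouths[top]))
        reliable = v[top] > threshold and dist <= gate_mm and v.sum() > 0
        info[m] = (reliable, top, dist, est)

    if strategy == "likelihood" and len(avail) == 2:
        (ma, mb) = list(avail)
        wa = 1 / sigmas[ma] ** 2
        wb = 1 / sigmas[mb] ** 2
        origin = (wa * avail[ma].origin + wb * avail[mb].origin) / (wa + wb)
        sig = np.sqrt(1 / (wa + wb))
        v = mpi(origin, mouths, sig, gate_mm)
        top = int(np.argmax(v))
        dist = float(np.linalg.norm(origin - mouths[top]))
        if v.sum() > 0 and v[top] > threshold and dist <= gate_mm:
            res.method, res.mouse_id = ma + "+" + mb, top
            res.residual_mm, res.origin = dist, origin
        else:
            res.reason = "low-MPI" if v.sum() > 0 else "distance-gate"
        return res

    if snr_gate is not None:
        cam = info.get("cam64")
        if cam is not None and cam[3].snr is not None \
                and cam[3].snr > snr_gate and cam[0]:
            _pick(res, "cam64", cam)
            return res

    reliable = {m: t for m, t in info.items() if t[0]}
    if not reliable:
        gated = any(res.mpi_per_method[m].sum() == 0 for m in avail)
        res.reason = "distance-gate" if gated else "low-MPI"
        return res
    if strategy == "mpi":
        pick = max(reliable, key=lambda m: res.mpi_per_method[m].max())
    elif strategy == "hybrid":
        # smaller residual to its own top mouse; ties prefer the beamformer
        pick = min(reliable, key=lambda m: (reliable[m][2], m != "cam64"))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    _pick(res, pick, reliable[pick])
    return res


def _pick(res: AssignmentResult, method: str, info) -> None:
    _, top, dist, est = info
    res.method, res.mouse_id = method, top
    res.residual_mm, res.origin = dist, est.origin


def mouths_at(tracks: list[MouseTrack], time_s: float,
              fraction: float = MOUTH_FRACTION_MANUAL) -> np.ndarray:
    """(n_mice, 2) mouth positions at the nearest frame to ``time_s``."""
    out = []
    for tr in tracks:
        k = tr.nearest_frame(time_s)
        out.append(mouth_point(tr.snout[k], tr.head_center[k], fraction))
    return np.asarray(out)


def min_snout_distance_at(tracks: list[MouseTrack], time_s: float) -> float:
    if len(tracks) < 2:
        return np.inf
    pts = [tr.snout[tr.nearest_frame(time_s)] for tr in tracks]
    d = np.inf
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = min(d, float(np.linalg.norm(pts[i] - pts[j])))
    return d


def estimate_systematic_offset(origins, mouths, min_count: int = 10):
    """Mean (estimate - mouth) vector over assigned calls, or None.

    Subtracting the returned 2-vector from the estimates re-centres the
    residual cloud (corrects small systematic array-placement shifts).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    mouths = np.atleast_2d(np.asarray(mouths, dtype=float))
    if len(origins) < min_count:
        return None
    return (origins - mouths).mean(axis=0)


def assign_dataset(segments: list[UsvSegment],
                   cam_estimates: list[LocalizationEstimate | None],
                   slim_estimates: list[LocalizationEstimate | None],
                   tracks: list[MouseTrack],
                   mouth_fraction: float = MOUTH_FRACTION_MANUAL,
                   calibration: CalibrationScale | None = None,
                   threshold: float = MPI_THRESHOLD,
                   gate_mm: float = DISTANCE_GATE_MM,
                   snr_gate: float | None = None,
                   strategy: str = "hybrid") -> list[AssignmentResult]:
    """Assign every call of a recording to a mouse (or to none).

    Pose is read at the temporal midpoint of each call (nearest frame).
    When ``calibration`` is None the scales are derived from this dataset's
    own far condition (all snouts > 100 mm apart; with a single mouse every
    call qualifies): per method, raw uncertainties are scaled so their mean
    matches the mean far-condition distance to the nearest mouth.
    """
    ests = {"cam64": cam_estimates, "slim": slim_estimates}
    n = len(segments)
    for v in ests.values():
        if len(v) != n:
            raise ValueError("estimate lists must match the segment list")
    mouths_per_usv = []
    far_mask = []
    for seg in segments:
        tm = seg.midpoint
        mouths_per_usv.append(mouths_at(tracks, tm, mouth_fraction))
        far_mask.append(min_snout_distance_at(tracks, tm) > FAR_CONDITION_MM)

    if calibration is None:
        scales = {}
        for m, lst in ests.items():
            raw = [e.uncertainty for e in lst if e is not None]
            far_res = [
                float(np.linalg.norm(
                    lst[k].origin - mouths_per_usv[k],
                    axis=1).min())
                for k in range(n) if far_mask[k] and lst[k] is not None
            ]
            scales[m] = calibrate_sigma(raw, far_res) if raw and far_res else 1.0
        calibration = CalibrationScale(scales)

    results = []
    for k, seg in enumerate(segments):
        estimates = {m: lst[k] for m, lst in ests.items()}
        sigmas = {m: calibration.sigma(m, e.uncertainty)
                  for m, e in estimates.items() if e is not None}
        results.append(hybrid_select(k, estimates, mouths_per_usv[k], sigmas,
                                     threshold=threshold, gate_mm=gate_mm,
                                     snr_gate=snr_gate, strategy=strategy))
    return results


def summarize_assignments(results: list[AssignmentResult],
                          ground_truth=None,
                          segment_to_truth=None) -> dict:
    """Assigned fraction, per-mouse counts and (with truth) accuracy."""
    n = len(results)
    assigned = [r for r in results if r.assigned]
    counts: dict[int, int] = {}
    for r in assigned:
        counts[r.mouse_id] = counts.get(r.mouse_id, 0) + 1
    out = {
        "n_usvs": n,
        "n_assigned": len(assigned),
        "assigned_fraction": len(assigned) / n if n else np.nan,
        "per_mouse_counts": counts,
    }
    if ground_truth is not None and segment_to_truth is not None:
        errs, correct = [], 0
        for r in assigned:
            k = segment_to_truth[r.usv_index]
            if k is None:
                continue
            ev = ground_truth[k]
            errs.append(float(np.linalg.norm(r.origin - ev.source[:2])))
            correct += int(r.mouse_id == ev.emitter_id)
        out["median_abs_error_mm"] = float(np.median(errs)) if errs else np.nan
        out["correct_emitter_rate"] = correct / len(errs) if errs else np.nan
    return out
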