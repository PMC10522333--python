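"""Spatial vocalization statistics.

Relative positions of interacting mice are expressed in a polar frame
centred on the emitter's snout: the radius is the snout-snout distance and
the angle is measured from the emitter's gaze direction (head-centre ->
snout line pointing at 0 degrees) to the receiver's snout.  Assuming no
left/right preference, angles are folded into the right hemispace
[0, 180] degrees and accumulated in raw-count polar histograms with 10
degree x 1 cm bins.  Group differences are assessed by rebuilding each
group's density-normalized histogram from bootstrap resamples and flagging
bins whose observed difference exceeds the most extreme bootstrap
deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ANGLE_BIN_DEG = 10.0
RADIUS_BIN_MM = 10.0
RADIUS_MAX_MM = 200.0


def relative_polar(emitter_snout, emitter_head_center, receiver_point):
    """(r_mm, alpha_deg) of a receiver point relative to the emitter.

    ``alpha`` is the unsigned angle from the emitter's gaze direction to the
    receiver, folded into [0, 180].
    """
    s = np.asarray(emitter_snout, dtype=float)
    h = np.asarray(emitter_head_center, dtype=float)
    p = np.asarray(receiver_point, dtype=float)
    gaze = s - h
    ng = np.linalg.norm(gaze)
    if ng == 0:
        raise ValueError("emitter gaze vector is zero")
    v = p - s
    r = float(np.linalg.norm(v))
    if r == 0:
        return 0.0, 0.0
    cosa = np.clip(np.dot(gaze, v) / (ng * r), -1.0, 1.0)
    return r, float(np.degrees(np.arccos(cosa)))


@dataclass
class PolarHistogram:
    """Raw-count polar histogram with an overflow radial bin."""

    angle_edges: np.ndarray       # degrees, [0 .. 180]
    radius_edges: np.ndarray      # mm, [0 .. r_max]; overflow row appended
    counts: np.ndarray            # (n_r + 1, n_a); last row = r >= r_max

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())

    def density(self) -> np.ndarray:
        """Counts normalized to sum 1 (uniform measure over bins)."""
        s = self.counts.sum()
        return self.counts / s if s > 0 else self.counts.astype(float)


def polar_histogram(points,
                    angle_bin: float = ANGLE_BIN_DEG,
                    radius_bin: float = RADIUS_BIN_MM,
                    radius_max: float = RADIUS_MAX_MM) -> PolarHistogram:
    """Bin (r, alpha) points with half-open [lo, hi) bins.

    Points at or beyond ``radius_max`` land in the overflow radial row, so
    total mass equals the number of input points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) if len(points) \
        else np.empty((0, 2))
    a_edges = np.arange(0, 180 + angle_bin / 2, angle_bin)
    r_edges = np.arange(0, radius_max + radius_bin / 2, radius_bin)
    n_a, n_r = len(a_edges) - 1, len(r_edges) - 1
    counts = np.zeros((n_r + 1, n_a), dtype=int)
    if len(pts):
        r, a = pts[:, 0], pts[:, 1]
        if np.any(r < 0):
            raise ValueError("negative radius")
        ia = np.minimum((a // angle_bin).astype(int), n_a - 1)  # 180 -> last
        ir = np.minimum((r // radius_bin).astype(int), n_r)     # overflow row
        np.add.at(counts, (ir, ia), 1)
    return PolarHistogram(angle_edges=a_edges, radius_edges=r_edges,
                          counts=counts)


def marginal_density(hists, axis: str = "radius"):
    """Marginal density over one polar axis, with SEM across recordings.

    ``hists`` is one PolarHistogram or a list (one per recording).  Returns
    (bin_centers, mean_density, sem); densities integrate to 1 over the
    finite bins (the overflow row is excluded from the radial marginal).
    """
    if isinstance(hists, PolarHistogram):
        hists = [hists]
    if not hists:
        raise ValueError("need at least one histogram")
    h0 = hists[0]
    if axis == "radius":
        edges = h0.radius_edges
        getm = lambda h: h.counts[:-1, :].sum(axis=1)
    elif axis == "angle":
        edges = h0.angle_edges
        getm = lambda h: h.counts.sum(axis=0)
    else:
        raise ValueError("axis must be 'radius' or 'angle'")
    width = np.diff(edges)
    dens = []
    for h in hists:
        m = getm(h).astype(float)
        s = (m * 1.0).sum()
        dens.append(m / (s * width) if s > 0 else m)
    dens = np.asarray(dens)
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / np.sqrt(len(dens)) if len(dens) > 1 \
        else np.zeros_like(mean)
    centers = edges[:-1] + width / 2
    return centers, mean, sem


def bootstrap_diff_significance(points_a, points_b, n_boot: int = 100,
                                level: float = 0.01, seed=None,
                                **hist_kw):
    """Per-bin significance mask for the difference of two polar densities.

    Each group's histogram (density-normalized to sum 1) is rebuilt
    ``n_boot`` times from resamples with replacement; per bin, the most
    extreme deviations from the observed density (up and down, at the
    ``level`` quantile — with 100 resamples at the default level this is
    the most extreme value itself) set the confidence limits.  A bin is
    flagged where the observed difference A - B exceeds the combined limits
    in either direction.

    Returns (mask, diff) where ``diff`` is the observed density difference.
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap resamples")
    rng = np.random.default_rng(seed)
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("both point sets must be non-empty")

    def density(pts):
        return polar_histogram(pts, **hist_kw).density()

    da, db = density(pa), density(pb)

    def limits(pts, obs):
        devs = np.empty((n_boot,) + obs.shape)
        for b in range(n_boot):
            res = pts[rng.integers(0, len(pts), len(pts))]
            devs[b] = density(res) - obs
        if n_boot * level <= 1:        # extreme-value limits
            lo, hi = devs.min(axis=0), devs.max(axis=0)
        else:
            lo = np.quantile(devs, level / 2, axis=0)
            hi = np.quantile(devs, 1 - level / 2, axis=0)
        return np.minimum(lo, 0.0), np.maximum(hi, 0.0)

    lo_a, hi_a = limits(pa, da)
    lo_b, hi_b = limits(pb, db)
    diff = da - db
    # A significantly above B: the observed gap exceeds what resampling
    # noise can produce in both groups combined (and vice versa).
    up = diff > hi_a - lo_b
    down = diff < lo_a - hi_b
    mask = (up | down) & (diff != 0)
    return mask, diff


def female_fraction(assignments, sexes: dict[int, str],
                    min_snout_distances=None,
                    distance_gate_mm: float | None = None) -> float:
    """Fraction of assigned calls attributed to female mice.

    ``assignments`` is a list of AssignmentResult; ``sexes`` maps mouse id
    to "female"/"male".  With ``distance_gate_mm`` set, only calls whose
    minimum pairwise snout distance (``min_snout_distances``, one value per
    call) exceeds the gate are counted.  Returns NaN when nothing qualifies.
    """
    n_f = n = 0
    for k, r in enumerate(assignments):
        if not r.assigned:
            continue
        if distance_gate_mm is not None:
            if min_snout_distances is None:
                raise ValueError("distance gating needs per-call distances")
            if min_snout_distances[k] <= distance_gate_mm:
                continue
        n += 1
        n_f += int(sexes[r.mouse_id] == "female")
    return n_f / n if n else np.nan


def classify_dominance(counts: dict[int, int],
                       sexes: dict[int, str]) -> dict[int, str]:
    """Dominant/subordinate labels for the same-sex pair of a triadic
    recording, based on who vocalized more.  Ties leave both unlabeled.
    """
    by_sex: dict[str, list[int]] = {}
    for mid, sex in sexes.items():
        by_sex.setdefault(sex, []).append(mid)
    pair = next((ids for ids in by_sex.values() if len(ids) == 2), None)
    if pair is None:
        return {}
    a, b = pair
    ca, cb = counts.get(a), counts.get(b)
    if ca is None or cb is None:
        raise ValueError("missing call counts for the same-sex pair")
    if ca == cb:
        return {}
    return {a: "dominant", b: "subordinate"} if ca > cb else \
        {a: "subordinate", b: "dominant"}


# -- thin wrappers over standard group tests (plumbing) ---------------------

def rank_sum(x, y):
    """Wilcoxon rank-sum (two-group, nonparametric)."""
    return stats.ranksums(x, y)


def kruskal(*groups):
    return stats.kruskal(*groups)


def spearman(x, y):
    return stats.spearmanr(x, y)


def bonferroni(p_values, n_tests: int | None = None):
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * (n_tests or p.size))
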