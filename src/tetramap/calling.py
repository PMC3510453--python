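"""Nucleosome midpoint calling on smoothed occupancy tracks.

Maxima of the smoothed signal are nucleosome midpoints (dyads); minima are
linkers.  Peak magnitude is not considered by default (min_prominence = 0):
every retained maximum becomes a call.  A positive prominence threshold
merges shallow peaks into their neighbors, which is useful at low coverage
where sampling noise creates spurious alternations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import NucleosomeCall, Replicon, SmoothedTrack

logger = logging.getLogger(__name__)

__all__ = [
    "Extrema",
    "OccupancyStateTrack",
    "RegionSet",
    "find_extrema",
    "call_nucleosomes",
    "peak_spacing",
    "nucleosome_density",
    "occupancy_states",
    "build_regions",
]

GENIC_UPSTREAM_BP = 40  # average promoter length prepended to transcribed spans


@dataclass
class Extrema:
    """Alternating maxima/minima positions on a track (sorted by position)."""

    maxima: np.ndarray
    minima: np.ndarray

    def ordered(self) -> list[tuple[int, str]]:
        out = [(int(p), "max") for p in self.maxima] + [(int(p), "min") for p in self.minima]
        return sorted(out)


@dataclass
class OccupancyStateTrack:
    """Per-base occupancy state encoded as 1 (occupied), 0.5 (transition), 0 (depleted)."""

    replicon: Replicon
    states: np.ndarray

    @property
    def values(self) -> np.ndarray:  # duck-types as a track for bedGraph export
        return self.states


@dataclass
class RegionSet:
    """Genic / non-genic partition of a replicon.

    Genic = expressed transcribed span plus 40 bp upstream of the 5' end
    (strand-aware); non-genic is the complement, so the two classes
    partition every base.
    """

    replicon: Replicon
    genic_mask: np.ndarray  # bool per base

    def class_of(self, pos: int) -> str:
        return "genic" if self.genic_mask[pos % self.replicon.length] else "non_genic"

    def intervals(self, cls: str) -> list[tuple[int, int]]:
        want = cls == "genic"
        mask = self.genic_mask == want
        change = np.flatnonzero(np.diff(mask.astype(int))) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(mask)]))
        return [(int(s), int(e)) for s, e in zip(starts, ends) if mask[s]]


def _runs(values: np.ndarray):
    """Run-length encode: (start, length, value) per run of equal values."""
    n = len(values)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [(int(s), int(e - s), float(values[s])) for s, e in zip(starts, ends)]


def find_extrema(smoothed: SmoothedTrack) -> Extrema:
    """Detect local maxima and minima; plateaus collapse to their center.

    On circular replicons the scan wraps, so the first and last extrema
    also alternate.  A constant track yields no extrema (with a warning).
    """
    v = np.asarray(smoothed.values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("track too short for extrema detection")
    runs = _runs(v)
    circular = smoothed.replicon.circular
    if len(runs) < 2:
        logger.warning("constant track on %s: no extrema", smoothed.replicon.name)
        return Extrema(np.array([], int), np.array([], int))
    if circular and len(runs) > 1 and runs[0][2] == runs[-1][2]:
        # merge the origin-spanning plateau into one wrapped run
        s_last, l_last, val = runs[-1]
        _s0, l0, _ = runs[0]
        runs = [(s_last, l_last + l0, val)] + runs[1:-1]
        if len(runs) < 2:
            logger.warning("constant track on %s: no extrema", smoothed.replicon.name)
            return Extrema(np.array([], int), np.array([], int))
    maxima, minima = [], []
    k = len(runs)
    for i, (start, length, val) in enumerate(runs):
        if circular:
            left = runs[(i - 1) % k][2]
            right = runs[(i + 1) % k][2]
        else:
            if i == 0 or i == k - 1:
                continue  # linear ends are not extrema
            left = runs[i - 1][2]
            right = runs[i + 1][2]
        center = (start + (length - 1) // 2) % n  # left-of-center for even plateaus
        if val > left and val > right:
            maxima.append(center)
        elif val < left and val < right:
            minima.append(center)
    return Extrema(np.array(sorted(maxima), int), np.array(sorted(minima), int))


def call_nucleosomes(smoothed: SmoothedTrack, min_prominence: float = 0.0) -> list[NucleosomeCall]:
    """One call per retained maximum, with flanking minima and prominence.

    prominence = peak value - max(flanking trough values).  Peaks below
    ``min_prominence`` are merged into a neighbor by removing the peak and
    its shallower flanking trough; merging repeats until all calls pass.
    """
    ext = find_extrema(smoothed)
    v = np.asarray(smoothed.values, dtype=float)
    seq = ext.ordered()
    if not seq:
        return []
    circular = smoothed.replicon.circular
    if not circular:
        # trim so the sequence starts and ends with minima (maxima need both flanks)
        while seq and seq[0][1] == "max":
            seq.pop(0)
        while seq and seq[-1][1] == "max":
            seq.pop()
    if min_prominence > 0:
        seq = _merge_shallow(seq, v, min_prominence, circular)

    calls: list[NucleosomeCall] = []
    k = len(seq)
    for i, (pos, kind) in enumerate(seq):
        if kind != "max":
            continue
        if circular:
            lpos = seq[(i - 1) % k][0]
            rpos = seq[(i + 1) % k][0]
        else:
            if i == 0 or i == k - 1:
                continue
            lpos, rpos = seq[i - 1][0], seq[i + 1][0]
        prom = float(v[pos] - max(v[lpos], v[rpos]))
        calls.append(
            NucleosomeCall(smoothed.replicon.name, pos, float(v[pos]), lpos, rpos, prom)
        )
    return calls


def _merge_shallow(seq, v, min_prominence, circular):
    """Iteratively remove the weakest sub-threshold peak and its shallower trough."""
    seq = list(seq)
    while True:
        k = len(seq)
        if k < (2 if circular else 3):
            break
        worst_i, worst_prom = None, None
        for i, (pos, kind) in enumerate(seq):
            if kind != "max":
                continue
            if circular:
                lv = v[seq[(i - 1) % k][0]]
                rv = v[seq[(i + 1) % k][0]]
            else:
                if i == 0 or i == k - 1:
                    continue
                lv, rv = v[seq[i - 1][0]], v[seq[i + 1][0]]
            prom = v[pos] - max(lv, rv)
            if prom < min_prominence and (worst_prom is None or prom < worst_prom):
                worst_i, worst_prom = i, prom
        if worst_i is None:
            break
        i = worst_i
        if circular:
            li, ri = (i - 1) % k, (i + 1) % k
        else:
            li, ri = i - 1, i + 1
        # remove the peak and the shallower (higher-valued) flanking trough
        drop_t = li if v[seq[li][0]] >= v[seq[ri][0]] else ri
        for j in sorted({i, drop_t}, reverse=True):
            seq.pop(j)
    return seq


def peak_spacing(calls, regions: RegionSet | None = None) -> dict:
    """Consecutive midpoint distances, overall and per genic/non-genic class.

    A distance is attributed to a class only when both flanking midpoints
    lie in intervals of that class; cross-class pairs are excluded.  On
    circular replicons the wrap-around pair is included.  Classes with no
    usable distance report ``None``.
    """
    mids = sorted(c.midpoint for c in calls)
    out: dict[str, dict | None] = {}
    if len(mids) < 2:
        out["all"] = None
        if regions is not None:
            out["genic"] = out["non_genic"] = None
        return out
    rep_circular = regions.replicon.circular if regions is not None else True
    n = regions.replicon.length if regions is not None else None
    pairs = list(zip(mids[:-1], mids[1:]))
    dists = [b - a for a, b in pairs]
    if rep_circular and n is not None and len(mids) >= 2:
        pairs.append((mids[-1], mids[0]))
        dists.append(n - mids[-1] + mids[0])
    out["all"] = _dist_stats(dists)
    if regions is not None:
        for cls in ("genic", "non_genic"):
            cls_d = [
                d
                for (a, b), d in zip(pairs, dists)
                if regions.class_of(a) == cls and regions.class_of(b) == cls
            ]
            out[cls] = _dist_stats(cls_d) if cls_d else None
    return out


def _dist_stats(dists):
    arr = np.asarray(dists, dtype=float)
    return {
        "n": len(arr),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    }


def nucleosome_density(calls, replicon: Replicon) -> float:
    """Called nucleosomes per kilobase of replicon."""
    return len(calls) / (replicon.length / 1000.0)


def occupancy_states(
    smoothed: SmoothedTrack, theta_occ: float = 2 / 3, theta_dep: float = 1 / 3
) -> OccupancyStateTrack:
    """Normalize occupancy into binary-like states: occupied / depleted / transition.

    Each peak-to-trough segment is min-max rescaled to [0, 1] so the state
    assignment is invariant to depth differences across the genome; bases
    at or above ``theta_occ`` are occupied (1), at or below ``theta_dep``
    depleted (0), in between transition (0.5).  Flat segments (peak equals
    trough) become transition with a warning.
    """
    if not (0 <= theta_dep < theta_occ <= 1):
        raise ValueError("need 0 <= theta_dep < theta_occ <= 1")
    v = np.asarray(smoothed.values, dtype=float)
    n = len(v)
    ext = find_extrema(smoothed)
    pts = sorted(int(p) for p in np.concatenate([ext.maxima, ext.minima]))
    if not smoothed.replicon.circular:
        pts = sorted({0, n - 1} | set(pts))  # linear ends bound the outer segments
    states = np.full(n, 0.5)
    if len(pts) < 2:
        logger.warning("no usable segments on %s: whole track transition", smoothed.replicon.name)
        return OccupancyStateTrack(smoothed.replicon, states)

    def assign(i0: int, i1: int, idx: np.ndarray) -> None:
        seg = v[idx]
        lo, hi = seg.min(), seg.max()
        if hi == lo:
            logger.warning("flat segment [%d, %d): transition", i0, i1)
            return
        scaled = (seg - lo) / (hi - lo)
        st = np.full(len(seg), 0.5)
        st[scaled >= theta_occ] = 1.0
        st[scaled <= theta_dep] = 0.0
        states[idx] = st

    for a, b in zip(pts[:-1], pts[1:]):
        assign(a, b, np.arange(a, b + 1))
    if smoothed.replicon.circular:
        idx = np.concatenate([np.arange(pts[-1], n), np.arange(0, pts[0] + 1)]) % n
        assign(pts[-1], pts[0], idx)
    else:
        if pts[0] > 0:
            assign(0, pts[0], np.arange(0, pts[0] + 1))
        if pts[-1] < n - 1:
            assign(pts[-1], n, np.arange(pts[-1], n))
    return OccupancyStateTrack(smoothed.replicon, states)


def build_regions(units, replicon: Replicon, upstream: int = GENIC_UPSTREAM_BP) -> RegionSet:
    """Partition a replicon into genic / non-genic classes from expressed units.

    Genic = transcribed span plus ``upstream`` bp before the 5' end,
    strand-aware; overlapping extensions merge naturally in the per-base
    mask.  Units without strand are excluded with a warning.
    """
    n = replicon.length
    mask = np.zeros(n, dtype=bool)
    for u in units:
        if u.strand not in ("+", "-"):
            logger.warning("unit [%d, %d) has no strand: excluded from regions", u.start, u.end)
            continue
        if u.strand == "+":
            s, e = u.start - upstream, u.end
        else:
            s, e = u.start, u.end + upstream
        if replicon.circular:
            idx = np.arange(s, e) % n
            mask[idx] = True
        else:
            mask[max(0, s) : min(n, e)] = True
    return RegionSet(replicon, mask)
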