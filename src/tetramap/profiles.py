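"""TSS/TTS-anchored occupancy profiles, NDR detection, and profile clustering.

Per-transcript rows are the smoothed occupancy over anchor +/- F bp
(default F = 200, i.e. a 400-bp window), orientation-flipped for minus
strand transcripts so positive offsets always point downstream of
transcription, and row-mean normalized so the aggregate is invariant to
per-region depth scaling.  The aggregate profile exposes the
nucleosome-depleted region (NDR) and its flanking -1/+1 nucleosomes;
per-transcript profiles are clustered hierarchically (average linkage,
1 - Pearson distance) and the largest k subclades extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "NDRCall",
    "ClusterResult",
    "anchored_matrix",
    "aggregate_profile",
    "detect_ndr",
    "compare_ndr",
    "cluster_profiles",
    "export_heatmap_tables",
]

FLANK_DEFAULT = 200


@dataclass
class ProfileMatrix:
    anchor: str  # "tss" or "tts"
    flank: int
    data: pd.DataFrame  # rows transcript ids, columns offsets -F..+F
    dropped: list[str] = field(default_factory=list)  # zero-signal rows


@dataclass
class NDRCall:
    anchor: str
    min_offset: int
    depth: float  # (flank mean - minimum) / flank mean, in [0, 1]
    width: int  # bp below the half-depth threshold
    minimum: float
    flank_mean: float


@dataclass
class ClusterResult:
    linkage: np.ndarray
    assignment: dict[str, int]  # id -> 1..k for the k largest subclades, 0 otherwise
    dropped: list[str]
    leaf_order: list[str]
    k: int


def anchored_matrix(track, units, anchor: str = "tss", flank: int = FLANK_DEFAULT,
                    normalize: str = "mean", ids=None) -> ProfileMatrix:
    """Build the transcripts x offsets occupancy matrix anchored at TSS or TTS.

    Rows for minus-strand units are reversed; each row is divided by its own
    mean (``normalize='mean'``), z-scored (``'zscore'``) or left raw
    (``'none'``).  Zero-signal rows are dropped and reported.
    """
    if anchor not in ("tss", "tts"):
        raise ValueError("anchor must be 'tss' or 'tts'")
    vals = np.asarray(track.values, dtype=float)
    n = len(vals)
    circular = track.replicon.circular
    offsets = np.arange(-flank, flank + 1)
    rows, row_ids, dropped = [], [], []
    for i, u in enumerate(units):
        uid = ids[i] if ids is not None else f"t{i}"
        if u.strand not in ("+", "-"):
            logger.warning("unit %s has no strand: skipped", uid)
            continue
        pos = u.tss if anchor == "tss" else u.tts
        idx = pos + offsets
        if circular:
            row = vals[idx % n]
        else:
            if idx[0] < 0 or idx[-1] >= n:
                logger.warning("unit %s window exceeds linear replicon: dropped", uid)
                dropped.append(uid)
                continue
            row = vals[idx]
        if u.strand == "-":
            row = row[::-1]
        if normalize == "mean":
            m = row.mean()
            if m == 0:
                dropped.append(uid)
                continue
            row = row / m
        elif normalize == "zscore":
            sd = row.std()
            if sd == 0:
                dropped.append(uid)
                continue
            row = (row - row.mean()) / sd
        elif normalize != "none":
            raise ValueError(f"unknown normalization {normalize!r}")
        rows.append(row)
        row_ids.append(uid)
    data = pd.DataFrame(rows, index=row_ids, columns=offsets)
    data.columns.name = "offset"
    return ProfileMatrix(anchor, flank, data, dropped)


def aggregate_profile(matrix: ProfileMatrix, n_boot: int = 0, ci: float = 0.95,
                      seed: int = 0) -> pd.DataFrame:
    """Column means of the profile matrix, with an optional seeded bootstrap
    percentile band over rows."""
    if matrix.data.empty:
        raise ValueError("empty profile matrix")
    mean = matrix.data.mean(axis=0)
    out = pd.DataFrame({"mean": mean})
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        arr = matrix.data.to_numpy()
        n = arr.shape[0]
        boots = np.empty((n_boot, arr.shape[1]))
        for b in range(n_boot):
            boots[b] = arr[rng.integers(0, n, n)].mean(axis=0)
        alpha = (1 - ci) / 2
        out["lo"] = np.quantile(boots, alpha, axis=0)
        out["hi"] = np.quantile(boots, 1 - alpha, axis=0)
    out.index.name = "offset"
    return out


def detect_ndr(aggregate: pd.DataFrame | pd.Series, anchor: str = "tss",
               search_window: tuple[int, int] = (-150, 50),
               width_frac: float = 0.5, flank_search: int = 100) -> NDRCall:
    """Locate the NDR in an aggregate profile.

    The minimum is taken inside ``search_window`` (offsets relative to the
    anchor).  Flanking local maxima are the nearest peaks left and right of
    the minimum within ``search_window`` widened by ``flank_search`` bp;
    depth = (mean of the two flank peaks - minimum) / flank mean, and width
    is the contiguous span around the minimum staying below
    minimum + width_frac * (flank mean - minimum).
    """
    series = aggregate["mean"] if isinstance(aggregate, pd.DataFrame) else aggregate
    offs = series.index.to_numpy()
    y = series.to_numpy(dtype=float)
    in_win = (offs >= search_window[0]) & (offs <= search_window[1])
    if not in_win.any():
        raise ValueError("search window outside the profiled offsets")
    win_idx = np.flatnonzero(in_win)
    min_val = y[in_win].min()
    # the NDR floor can be an exact tie (zero occupancy): report the center
    # of the contiguous tied run rather than its leftmost position
    tied = win_idx[np.abs(y[win_idx] - min_val) <= 1e-9]
    runs = np.split(tied, np.flatnonzero(np.diff(tied) > 1) + 1)
    run = max(runs, key=len)
    min_idx = int(run[(len(run) - 1) // 2])
    min_off = int(offs[min_idx])
    lo_bound = search_window[0] - flank_search
    hi_bound = search_window[1] + flank_search
    peaks, _ = signal.find_peaks(y)
    left = [p for p in peaks if offs[p] < min_off and offs[p] >= lo_bound]
    right = [p for p in peaks if offs[p] > min_off and offs[p] <= hi_bound]
    if not left or not right:
        raise ValueError(
            f"no flanking maxima inside [{lo_bound}, {hi_bound}]; widen the search window"
        )
    lpk = left[-1]  # nearest on each side
    rpk = right[0]
    flank_mean = float((y[lpk] + y[rpk]) / 2.0)
    minimum = float(y[min_idx])
    if flank_mean <= 0:
        raise ValueError("non-positive flank occupancy")
    depth = (flank_mean - minimum) / flank_mean
    thresh = minimum + width_frac * (flank_mean - minimum)
    lo = min_idx
    while lo > 0 and y[lo - 1] < thresh:
        lo -= 1
    hi = min_idx
    while hi < len(y) - 1 and y[hi + 1] < thresh:
        hi += 1
    return NDRCall(anchor, min_off, float(depth), int(hi - lo + 1), minimum, flank_mean)


def compare_ndr(tss_call: NDRCall, tts_call: NDRCall,
                tss_matrix: ProfileMatrix | None = None,
                tts_matrix: ProfileMatrix | None = None,
                n_boot: int = 200, seed: int = 0, **ndr_kwargs) -> dict:
    """Compare the 5' (TSS) and 3' (TTS) NDRs.

    Reports depth and width differences (5' minus 3'); when the profile
    matrices are supplied, bootstrap resampling of rows yields percentile
    confidence intervals for both differences.
    """
    report = {
        "depth_5p": tss_call.depth,
        "depth_3p": tts_call.depth,
        "depth_diff": tss_call.depth - tts_call.depth,
        "width_5p": tss_call.width,
        "width_3p": tts_call.width,
        "width_diff": tss_call.width - tts_call.width,
    }
    if tss_matrix is not None and tts_matrix is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        ddiffs, wdiffs = [], []
        a5 = tss_matrix.data.to_numpy()
        a3 = tts_matrix.data.to_numpy()
        cols5 = tss_matrix.data.columns
        cols3 = tts_matrix.data.columns
        for _ in range(n_boot):
            try:
                m5 = pd.Series(a5[rng.integers(0, len(a5), len(a5))].mean(axis=0), index=cols5)
                m3 = pd.Series(a3[rng.integers(0, len(a3), len(a3))].mean(axis=0), index=cols3)
                c5 = detect_ndr(m5, "tss", **ndr_kwargs)
                c3 = detect_ndr(m3, "tts", **ndr_kwargs)
            except ValueError:
                continue
            ddiffs.append(c5.depth - c3.depth)
            wdiffs.append(c5.width - c3.width)
        if ddiffs:
            report["depth_diff_ci"] = (
                float(np.quantile(ddiffs, 0.025)),
                float(np.quantile(ddiffs, 0.975)),
            )
            report["width_diff_ci"] = (
                float(np.quantile(wdiffs, 0.025)),
                float(np.quantile(wdiffs, 0.975)),
            )
            report["n_boot_used"] = len(ddiffs)
    return report


def cluster_profiles(matrix: ProfileMatrix, k: int = 6, min_size: int = 2) -> ClusterResult:
    """Hierarchical clustering of per-transcript profiles into subclades.

    Distance is 1 - Pearson correlation between rows; linkage is average.
    The tree is cut at the most-merged level yielding at least k clusters
    whose k largest members are non-trivial (>= ``min_size`` rows; a lone
    outlier row is not a subclade, so the cut descends past it).  The k
    largest subclades (by size, ties by first row occurrence) are labeled
    1..k; remaining rows get label 0.  Zero-variance rows are dropped
    before clustering and reported.
    """
    data = matrix.data
    sds = data.std(axis=1)
    keep = sds > 0
    dropped = list(data.index[~keep])
    data = data.loc[keep]
    if len(data) < k:
        raise ValueError(f"need at least k={k} non-degenerate rows, have {len(data)}")
    d = pdist(data.to_numpy(), metric="correlation")
    Z = hierarchy.linkage(d, method="average")
    heights = np.unique(Z[:, 2])
    labels = None
    best, best_kth = None, -1
    for t in heights[::-1]:
        cand = hierarchy.fcluster(Z, t=t, criterion="distance")
        if cand.max() < k:
            continue
        kth = sorted(np.bincount(cand)[1:], reverse=True)[k - 1]
        if kth >= min_size:
            labels = cand
            break
        if kth > best_kth:
            best, best_kth = cand, kth
    if labels is None:
        labels = best if best is not None else hierarchy.fcluster(Z, t=-1.0, criterion="distance")
    # rank clusters by size; ties broken by first occurrence in row order
    order: dict[int, int] = {}
    sizes: dict[int, int] = {}
    for i, lab in enumerate(labels):
        sizes[lab] = sizes.get(lab, 0) + 1
        order.setdefault(lab, i)
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], order[lab]))
    relabel = {lab: (r + 1 if r < k else 0) for r, lab in enumerate(ranked)}
    assignment = {rid: relabel[lab] for rid, lab in zip(data.index, labels)}
    leaf_idx = hierarchy.leaves_list(Z)
    leaf_order = [data.index[i] for i in leaf_idx]
    return ClusterResult(Z, assignment, dropped, leaf_order, k)


def export_heatmap_tables(matrix: ProfileMatrix, clustering: ClusterResult,
                          matrix_path, assign_path) -> None:
    """Write the matrix reordered by dendrogram leaf order plus the subclade
    assignments, both as TSV."""
    ordered = matrix.data.loc[clustering.leaf_order]
    ordered.to_csv(matrix_path, sep="\t", index_label="id")
    assign = pd.DataFrame(
        {
            "id": clustering.leaf_order,
            "subclade": [clustering.assignment[i] for i in clustering.leaf_order],
        }
    )
    assign.to_csv(assign_path, sep="\t", index=False)
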