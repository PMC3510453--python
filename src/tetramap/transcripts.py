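"""Refinement of predicted gene annotations into expressed transcript units.

RNA-seq per-base coverage drives four steps: (1) classify which predicted
annotations are detectably expressed; (2) trim/extend each expressed
annotation's 5' and 3' boundaries to the edges of its high-coverage
plateau; (3) merge same-strand neighbors whose intergenic gap is fully
covered (operon run-through transcription); (4) call novel units from
covered runs that overlap no annotation.  Thresholds are explicit,
documented stand-ins: expression requires mean coverage >= ``c_min``
(default 5x) and the plateau threshold is max(3, t_rel * median coverage
within the annotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Annotation, CoverageTrack, TranscriptUnit

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionSummary",
    "classify_expressed",
    "trim_boundaries",
    "merge_units",
    "detect_novel",
    "refine_transcripts",
    "summarize",
]

C_MIN_DEFAULT = 5.0
T_REL_DEFAULT = 0.1
T_FLOOR = 3.0
MAX_EXT_DEFAULT = 250
MIN_NOVEL_LEN_DEFAULT = 100


@dataclass
class ExpressionSummary:
    n_predicted: int
    n_confirmed: int
    n_merged_into: int
    n_novel: int
    fraction_expressed: float


def _mean_cov(cov: np.ndarray, start: int, end: int) -> float:
    return float(cov[start:end].mean())


def classify_expressed(annotations, rna_coverage: CoverageTrack, c_min: float = C_MIN_DEFAULT):
    """Flag annotations as expressed when mean per-base coverage >= c_min.

    Returns dict annotation id -> (expressed: bool, mean_coverage: float).
    """
    cov = rna_coverage.values
    n = rna_coverage.replicon.length
    out: dict[str, tuple[bool, float]] = {}
    for a in annotations:
        if not (0 <= a.start < a.end <= n):
            raise ValueError(f"annotation {a.id} outside replicon")
        m = _mean_cov(cov, a.start, a.end)
        out[a.id] = (m >= c_min, m)
    return out


def _plateau_threshold(cov, start, end, t_rel):
    return max(T_FLOOR, t_rel * float(np.median(cov[start:end])))


def trim_boundaries(
    annotation: Annotation,
    rna_coverage: CoverageTrack,
    t_rel: float = T_REL_DEFAULT,
    max_ext: int = MAX_EXT_DEFAULT,
    left_limit: int | None = None,
    right_limit: int | None = None,
) -> tuple[int, int] | None:
    """Adjust an expressed annotation's ends to its coverage plateau.

    Each end first shrinks inward while per-base coverage is below the
    plateau threshold, then extends outward while coverage stays at or
    above it, capped at ``max_ext`` bp and stopping before the next
    same-strand annotation (``left_limit`` / ``right_limit`` as absolute
    coordinates).  Returns the adjusted (start, end) or None when trimming
    collapses the unit.
    """
    cov = rna_coverage.values
    n = len(cov)
    t = _plateau_threshold(cov, annotation.start, annotation.end, t_rel)
    start, end = annotation.start, annotation.end
    # shrink
    while start < end and cov[start] < t:
        start += 1
    while end > start and cov[end - 1] < t:
        end -= 1
    if start >= end:
        logger.warning("annotation %s collapsed during trimming: dropped", annotation.id)
        return None
    # extend
    lo_cap = max(0 if left_limit is None else left_limit, start - max_ext, 0)
    while start > lo_cap and cov[start - 1] >= t:
        start -= 1
    hi_cap = min(n if right_limit is None else right_limit, end + max_ext, n)
    while end < hi_cap and cov[end] >= t:
        end += 1
    return start, end


def merge_units(units, rna_coverage: CoverageTrack, t: float = C_MIN_DEFAULT):
    """Merge adjacent same-strand units whose gap is covered everywhere >= t.

    ``units`` are (start, end, annotation) triples on one strand, sorted
    and non-overlapping.  Merging is transitive, so operon chains collapse
    into a single unit.  Returns a list of TranscriptUnits (merged or
    confirmed).
    """
    cov = rna_coverage.values
    out: list[TranscriptUnit] = []
    chain: list[tuple[int, int, Annotation]] = []

    def flush():
        if not chain:
            return
        s = chain[0][0]
        e = chain[-1][1]
        ids = tuple(a.id for _, _, a in chain)
        status = "merged" if len(chain) > 1 else "confirmed"
        out.append(
            TranscriptUnit(
                chain[0][2].replicon_name, s, e, chain[0][2].strand, status, ids,
                _mean_cov(cov, s, e),
            )
        )

    for item in sorted(units, key=lambda x: x[0]):
        if chain:
            gap_start, gap_end = chain[-1][1], item[0]
            covered = gap_start >= gap_end or bool(np.all(cov[gap_start:gap_end] >= t))
            if covered:
                chain.append(item)
                continue
            flush()
            chain = []
        chain.append(item)
    flush()
    return out


def detect_novel(
    rna_coverage: CoverageTrack,
    units,
    t: float = C_MIN_DEFAULT,
    min_len: int = MIN_NOVEL_LEN_DEFAULT,
) -> list[TranscriptUnit]:
    """Call novel units: maximal covered runs (>= t) of length >= min_len
    overlapping no refined unit.  Novel units carry strand '.'."""
    cov = rna_coverage.values
    n = len(cov)
    mask = cov >= t
    change = np.flatnonzero(np.diff(mask.astype(int))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    runs = [(int(s), int(e)) for s, e in zip(starts, ends) if mask[s]]
    if rna_coverage.replicon.circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n:
        # origin-spanning run: report as one unit anchored at the tail half
        s_tail, _ = runs[-1]
        _, e_head = runs[0]
        runs = runs[1:-1] + [(s_tail, n + e_head)]
    occupied = sorted((u.start, u.end) for u in units)
    novel: list[TranscriptUnit] = []
    for s, e in runs:
        if e - s < min_len:
            continue
        s_mod, e_mod = s % n, ((e - 1) % n) + 1
        if any(_overlaps_circular(s, e, us, ue, n) for us, ue in occupied):
            continue
        novel.append(
            TranscriptUnit(
                rna_coverage.replicon.name,
                s_mod,
                min(e, n) if e <= n else e_mod,
                ".",
                "novel",
                (),
                float(cov[np.arange(s, e) % n].mean()),
            )
        )
    return novel


def _overlaps_circular(s, e, us, ue, n):
    if e <= n:
        return s < ue and us < e
    # wrapped run [s, n) + [0, e-n)
    return (s < ue and us < n) or (0 < ue and us < e - n)


def refine_transcripts(
    annotations,
    rna_coverage: CoverageTrack,
    c_min: float = C_MIN_DEFAULT,
    t_rel: float = T_REL_DEFAULT,
    max_ext: int = MAX_EXT_DEFAULT,
    merge_t: float | None = None,
    min_novel_len: int = MIN_NOVEL_LEN_DEFAULT,
):
    """Run the full refinement: classify, trim, merge, detect novel.

    Returns (units, expressed_flags) where units includes confirmed, merged
    and novel TranscriptUnits and expressed_flags is the classify_expressed
    mapping over the input annotations.
    """
    merge_t = c_min if merge_t is None else merge_t
    flags = classify_expressed(annotations, rna_coverage, c_min)
    by_strand: dict[str, list] = {}
    anns_sorted = sorted(annotations, key=lambda a: a.start)
    for strand in ("+", "-"):
        strand_anns = [a for a in anns_sorted if a.strand == strand]
        trimmed = []
        for i, a in enumerate(strand_anns):
            if not flags[a.id][0]:
                continue
            left = strand_anns[i - 1].end if i > 0 else None
            right = strand_anns[i + 1].start if i + 1 < len(strand_anns) else None
            bounds = trim_boundaries(a, rna_coverage, t_rel, max_ext, left, right)
            if bounds is not None:
                trimmed.append((bounds[0], bounds[1], a))
        by_strand[strand] = trimmed
    units: list[TranscriptUnit] = []
    for strand in ("+", "-"):
        units.extend(merge_units(by_strand[strand], rna_coverage, merge_t))
    units.extend(detect_novel(rna_coverage, units, merge_t, min_novel_len))
    return units, flags


def summarize(units, annotations, flags) -> ExpressionSummary:
    """Pipeline bookkeeping: confirmed / merged / novel counts and the
    expressed fraction of predicted annotations."""
    absorbed = {sid for u in units for sid in u.source_ids}
    n_confirmed = sum(1 for a in annotations if a.id in absorbed)
    n_merged_into = sum(len(u.source_ids) for u in units if u.status == "merged")
    n_novel = sum(1 for u in units if u.status == "novel")
    n_expressed = sum(1 for a in annotations if flags[a.id][0])
    n_pred = len(annotations)
    return ExpressionSummary(
        n_predicted=n_pred,
        n_confirmed=n_confirmed,
        n_merged_into=n_merged_into,
        n_novel=n_novel,
        fraction_expressed=n_expressed / n_pred if n_pred else 0.0,
    )
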