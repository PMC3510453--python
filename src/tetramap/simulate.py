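"""Synthetic genome / chromatin / transcriptome generator with ground truth.

The generator emulates the study system: a circular, GC-rich (~65%) genome
densely packed with genes; nucleosomes protecting 50-60 bp with mean
midpoint spacing ~68.5 bp inside genic regions (transcribed span + 40 bp
upstream) and ~76.1 bp elsewhere; nucleosome-depleted regions (NDRs) at the
TSS and TTS of expressed transcripts, the 5' NDR wider and deeper, each
flanked by positioned -1/+1 nucleosomes; dyad-proximal GC enrichment
ramping from ~61% at the protected-fragment edge to ~75% at the midpoint;
and an RNA-seq coverage landscape of plateaus over expressed units, with
operon run-through and unannotated (novel) units.  A featureless naked-DNA
control with the same fragment count is emitted alongside.

Everything derives from one seeded numpy Generator, so a fixed seed gives a
byte-identical bundle.  Every planted feature is recorded in ground-truth
tables so each pipeline stage can be scored for recovery.

Mechanics worth knowing when interpreting recovery numbers:

* Dyads come from a single circular renewal walk whose step distribution
  switches between the genic and non-genic normals.  NDRs are implemented
  by deleting walk dyads inside the NDR zone (plus a margin of half the
  local mean spacing) and planting -1/+1 anchor dyads 15 bp outside the
  zone edges; the margin is sized so anchor-adjacent spacings keep the
  class mean.  The 3' NDR retains a fraction of interior dyads
  (``ndr3_scale``), which is what makes it shallower.
* Fragment counts per dyad are Poisson with rate depth * spacing / mean
  fragment length, so genome-average coverage matches ``depth``.
* When ``profile_classes`` is set, each expressed transcript is assigned a
  class k (round-robin) and its TSS +/- 260 bp is filled with phase-locked
  dyads at arm spacing 400/k instead of walk dyads; this is the clustering
  benchmark and deliberately distorts spacing statistics, so it is off by
  default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Annotation, CoverageTrack, Fragment, FragmentSet, Replicon
from .dyadseq import DyadWindowSet
from . import io as tio

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimBundle",
    "simulate",
    "write_bundle",
    "truth_compare",
    "compare_units",
    "expected_refined_spans",
    "simulate_dyad_windows",
]

ANCHOR_OFFSET = 15  # bp between an NDR zone edge and its -1/+1 anchor dyad


@dataclass
class SimulationConfig:
    seed: int
    genome_length: int = 200_000
    gc: float = 0.65
    circular: bool = True
    replicon_name: str = "chr"
    n_transcripts: int = 120
    transcript_len_range: tuple[int, int] = (500, 1200)
    fraction_expressed: float = 0.75
    genic_spacing: tuple[float, float] = (68.5, 6.0)
    nongenic_spacing: tuple[float, float] = (76.1, 8.0)
    fragment_len_range: tuple[int, int] = (50, 60)
    jitter_sd: float = 3.0
    depth: float = 30.0
    ndr5_width: int = 120
    ndr5_scale: float = 0.0  # fraction of interior dyads retained (0 = fully depleted)
    ndr5_center: int = -50  # offset from TSS, negative = upstream
    ndr3_width: int = 70
    ndr3_scale: float = 0.3
    ndr3_center: int = 0  # at the TTS
    dyad_gc_edge: float = 0.61
    dyad_gc_mid: float = 0.75
    dyad_gc_halfwidth: int = 30
    n_operons: int = 8
    operon_size_range: tuple[int, int] = (2, 4)
    operon_gap_range: tuple[int, int] = (20, 40)
    intergenic_gap_range: tuple[int, int] = (260, 500)
    divergent_gap_range: tuple[int, int] = (620, 820)  # head-to-head promoter pairs
    n_novel: int = 10
    novel_len_range: tuple[int, int] = (150, 400)
    rna_depth: float = 50.0
    rna_sigma: float = 0.5
    ragged_bp: int = 10
    utr5_range: tuple[int, int] = (20, 60)
    utr3_range: tuple[int, int] = (0, 20)
    genic_upstream: int = 40
    profile_classes: tuple[int, ...] | None = None  # e.g. (4, 5, 6)
    periodicity: tuple[float, float] | None = None  # (amplitude, period bp)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.gc, self.fraction_expressed):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SimBundle:
    config: SimulationConfig
    replicon: Replicon
    annotations: list[Annotation]
    fragments: FragmentSet
    mnase: CoverageTrack
    naked: CoverageTrack
    rna: CoverageTrack
    truth_dyads: pd.DataFrame  # midpoint, region_class, kind, profile_class
    truth_units: pd.DataFrame  # per-gene + novel rows
    genic_mask: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# generation


def _plan_groups(cfg: SimulationConfig, rng) -> list[int]:
    lo, hi = cfg.operon_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_operons)]
    if sum(sizes) > cfg.n_transcripts:
        raise ValueError("operons demand more transcripts than configured")
    sizes += [1] * (cfg.n_transcripts - sum(sizes))
    return [int(s) for s in rng.permutation(sizes)]


def _place_units(cfg: SimulationConfig, rng):
    """Lay out transcript groups and novel units along the genome."""
    group_sizes = _plan_groups(cfg, rng)
    n_groups = len(group_sizes)
    novel_every = max(1, n_groups // (cfg.n_novel + 1)) if cfg.n_novel else 0
    rows = []  # dicts: unit-level truth
    pos = int(rng.integers(200, 400))
    L = cfg.genome_length
    uid = 0
    novel_placed = 0
    prev_gene_strand = None
    for gi, size in enumerate(group_sizes):
        if cfg.n_novel and novel_placed < cfg.n_novel and gi > 0 and gi % novel_every == 0:
            nl = int(rng.integers(cfg.novel_len_range[0], cfg.novel_len_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if pos + nl > L - 600:
                raise ValueError("infeasible packing: genome too short for configured units")
            rows.append(
                dict(id=f"novel{novel_placed:03d}", start=pos, end=pos + nl, strand=strand,
                     operon=-1, novel=True, expressed=True)
            )
            novel_placed += 1
            pos += nl + int(rng.integers(*cfg.intergenic_gap_range))
            prev_gene_strand = None  # a novel unit breaks promoter adjacency
        strand = "+" if rng.random() < 0.5 else "-"
        # head-to-head (divergent) promoter pairs get enough room that the
        # two 5' NDR neighborhoods do not overlap
        if gi > 0 and prev_gene_strand == "-" and strand == "+":
            pos += int(rng.integers(*cfg.divergent_gap_range)) - 260
        members = []
        for j in range(size):
            tl = int(rng.integers(cfg.transcript_len_range[0], cfg.transcript_len_range[1] + 1))
            if pos + tl > L - 300:
                raise ValueError("infeasible packing: genome too short for configured units")
            members.append((pos, pos + tl))
            pos += tl
            if j < size - 1:
                pos += int(rng.integers(*cfg.operon_gap_range))
        pos += int(rng.integers(*cfg.intergenic_gap_range))
        prev_gene_strand = strand
        for start, end in members:
            rows.append(
                dict(id=f"gene{uid:04d}", start=start, end=end, strand=strand,
                     operon=gi, novel=False, expressed=False)
            )
            uid += 1
    if novel_placed < cfg.n_novel:
        raise ValueError("infeasible packing: could not place all novel units")
    units = pd.DataFrame(rows)

    # expression: exact target count, decided at group level so operons are uniform
    target = int(round(cfg.fraction_expressed * cfg.n_transcripts))
    genes = units[~units.novel]
    group_ids = genes.operon.unique()
    n_expressed = 0
    expressed_groups = set()
    for g in rng.permutation(group_ids):
        size = int((genes.operon == g).sum())
        if n_expressed + size <= target:
            expressed_groups.add(int(g))
            n_expressed += size
        if n_expressed == target:
            break
    units.loc[~units.novel, "expressed"] = [
        int(g) in expressed_groups for g in units.loc[~units.novel, "operon"]
    ]
    return units


def _tss_tts(row) -> tuple[int, int]:
    if row.strand == "+":
        return int(row.start), int(row.end) - 1
    return int(row.end) - 1, int(row.start)


def _build_genic_mask(cfg: SimulationConfig, units: pd.DataFrame) -> np.ndarray:
    """Genic = expressed operon-level span + 40 bp upstream of the 5' end."""
    L = cfg.genome_length
    mask = np.zeros(L, dtype=bool)
    genes = units[(~units.novel) & units.expressed]
    for g, grp in genes.groupby("operon"):
        s, e = int(grp.start.min()), int(grp.end.max())
        strand = grp.strand.iloc[0]
        if strand == "+":
            lo, hi = s - cfg.genic_upstream, e
        else:
            lo, hi = s, e + cfg.genic_upstream
        mask[np.arange(lo, hi) % L] = True
    return mask


def simulate(config: SimulationConfig) -> SimBundle:
    """Generate the full bundle: genome, annotations, fragments, coverage
    tracks and ground-truth tables."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    base_p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    genome = rng.choice(np.array(list("ACGT")), size=L, p=base_p)

    units = _place_units(cfg, rng)
    genic_mask = _build_genic_mask(cfg, units)

    # annotations: predicted ORFs miss the UTRs of expressed genes
    annotations: list[Annotation] = []
    ann_bounds = {}
    for row in units.itertuples():
        if row.novel:
            continue
        if row.expressed:
            utr5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
            utr3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        else:
            utr5 = utr3 = 0
        if row.strand == "+":
            a, b = row.start + utr5, row.end - utr3
        else:
            a, b = row.start + utr3, row.end - utr5
        annotations.append(Annotation(row.id, cfg.replicon_name, a, b, row.strand))
        ann_bounds[row.id] = (a, b)
    units["ann_start"] = [ann_bounds.get(i, (pd.NA, pd.NA))[0] for i in units.id]
    units["ann_end"] = [ann_bounds.get(i, (pd.NA, pd.NA))[1] for i in units.id]

    # --- NDR zones and dyad placement -------------------------------------
    mu_g, sd_g = cfg.genic_spacing
    mu_n, sd_n = cfg.nongenic_spacing
    mu_at = np.where(genic_mask, mu_g, mu_n)
    sd_at = np.where(genic_mask, sd_g, sd_n)

    # NDRs belong to transcription units, so operons get one 5' and one 3'
    # zone at the ends of the whole operon span, not at interior junctions
    spans = expected_refined_spans(units)
    class_cycle = list(cfg.profile_classes) if cfg.profile_classes else []
    profile_class_of: dict[int, int] = {}
    zones: list[dict] = []  # lo <= hi in genome coords; dyad-free except `scale`
    arm_dyads: list[tuple[int, int]] = []  # phase-locked TSS arms (classed runs)
    for ci, row in enumerate(spans.itertuples()):
        tss, tts = _tss_tts(row)
        sign = 1 if row.strand == "+" else -1
        c5 = tss + sign * cfg.ndr5_center
        lo5, hi5 = c5 - cfg.ndr5_width // 2, c5 + cfg.ndr5_width // 2
        c3 = tts + sign * cfg.ndr3_center
        lo3, hi3 = c3 - cfg.ndr3_width // 2, c3 + cfg.ndr3_width // 2
        if class_cycle:
            k = class_cycle[ci % len(class_cycle)]
            profile_class_of[int(row.operon)] = k
            # the whole TSS window is reserved for phase-locked arm dyads at
            # spacing 400/k, which is what the clustering benchmark separates
            zones.append(dict(lo=tss - 300, hi=tss + 300, scale=0.0, anchors=False))
            s = 400.0 / k
            down_edge = hi5 if sign == 1 else lo5
            up_edge = lo5 if sign == 1 else hi5
            # first dyad half a class-spacing out from the NDR edge, so the
            # -1/+1 positions themselves are class-specific
            off = s / 2.0
            while off <= 300 - cfg.ndr5_width // 2:
                arm_dyads.append((int(round(down_edge + sign * off)) % L, k))
                arm_dyads.append((int(round(up_edge - sign * off)) % L, k))
                off += s
        else:
            zones.append(dict(lo=lo5, hi=hi5, scale=cfg.ndr5_scale, anchors=True))
        zones.append(dict(lo=lo3, hi=hi3, scale=cfg.ndr3_scale, anchors=True))

    zones.sort(key=lambda z: z["lo"] % L)
    merged_zones: list[dict] = []
    for z in zones:
        zlo, zhi = z["lo"] % L, z["lo"] % L + (z["hi"] - z["lo"])
        if merged_zones and zlo <= merged_zones[-1]["hi"] + 2 * ANCHOR_OFFSET:
            prev = merged_zones[-1]
            prev["hi"] = max(prev["hi"], zhi)
            prev["scale"] = min(prev["scale"], z["scale"])
            prev["anchors"] = prev["anchors"] or z["anchors"]
        else:
            merged_zones.append(dict(lo=zlo, hi=zhi, scale=z["scale"], anchors=z["anchors"]))

    anchors: list[tuple[int, int]] = [
        (p % L, 0)
        for z in merged_zones
        if z["anchors"]
        for p in (z["lo"] - ANCHOR_OFFSET, z["hi"] + ANCHOR_OFFSET)
    ]
    interior: list[int] = []
    for z in merged_zones:
        if z["scale"] > 0:
            center = (z["lo"] + z["hi"]) // 2 % L
            lam = z["scale"] * (z["hi"] - z["lo"] + 1) / mu_at[center]
            for _ in range(int(rng.poisson(lam))):
                interior.append(int(rng.integers(z["lo"], z["hi"] + 1)) % L)

    def tile_segment(a: int, b: int) -> list[int]:
        """Dyad positions strictly inside (a, b): class-mean spacings drawn
        sequentially, then rescaled (factor near 1) to tile the segment
        exactly, so no artificially short or long gap remains at either end."""
        length = b - a
        if length < 30:
            return []
        steps: list[float] = []
        s = 0.0
        while s < length:
            p = int(a + s) % L
            steps.append(max(20.0, float(rng.normal(mu_at[p], sd_at[p]))))
            s += steps[-1]
        if len(steps) > 1 and abs((s - steps[-1]) - length) < abs(s - length):
            s -= steps.pop()
        scale = length / s
        out = []
        acc = 0.0
        for st in steps[:-1]:
            acc += st * scale
            out.append(int(round(a + acc)) % L)
        return out

    tiled: list[int] = []
    if merged_zones:
        for zi, z in enumerate(merged_zones):
            nxt = merged_zones[(zi + 1) % len(merged_zones)]
            a = z["hi"] + ANCHOR_OFFSET
            b = nxt["lo"] - ANCHOR_OFFSET + (L if zi == len(merged_zones) - 1 else 0)
            tiled.extend(tile_segment(a, b))
    else:
        start = int(rng.integers(0, 100))
        tiled.extend(tile_segment(start, start + L))

    dyad_rows = [dict(midpoint=p, kind="walk", profile_class=0) for p in tiled + interior]
    dyad_rows += [dict(midpoint=p, kind="anchor", profile_class=k)
                  for p, k in anchors + arm_dyads]
    truth_dyads = pd.DataFrame(dyad_rows).drop_duplicates("midpoint").sort_values("midpoint")
    truth_dyads["region_class"] = np.where(
        genic_mask[truth_dyads.midpoint % L], "genic", "non_genic"
    )
    truth_dyads = truth_dyads.reset_index(drop=True)

    # --- dyad-proximal GC ramp (and optional periodic AA planting) --------
    hw = cfg.dyad_gc_halfwidth
    offs = np.arange(-hw, hw + 1)
    ramp = cfg.dyad_gc_edge + (cfg.dyad_gc_mid - cfg.dyad_gc_edge) * (1 - np.abs(offs) / hw)
    in_window = np.zeros(L, dtype=bool)
    for mid in truth_dyads.midpoint:
        idx = (mid + offs) % L
        in_window[idx] = True
        is_gc = rng.random(len(offs)) < ramp
        strong = rng.random(len(offs)) < 0.5
        genome[idx] = np.where(is_gc, np.where(strong, "G", "C"), np.where(strong, "A", "T"))
    # dyad windows tile most of the genome above the global GC target, so the
    # linker bases are resampled AT-shifted to keep genome-wide GC on target
    n_linker = int((~in_window).sum())
    if n_linker > 0:
        gc_in_windows = int(np.isin(genome[in_window], ("G", "C")).sum())
        p_linker = float(np.clip((cfg.gc * L - gc_in_windows) / n_linker, 0.0, 1.0))
        lp = np.array([(1 - p_linker) / 2, p_linker / 2, p_linker / 2, (1 - p_linker) / 2])
        genome[~in_window] = rng.choice(np.array(list("ACGT")), size=n_linker, p=lp)
    if cfg.periodicity is not None:
        amp, period = cfg.periodicity
        per_offs = np.arange(-hw, hw, int(round(period)))
        for mid in truth_dyads.midpoint:
            hit = rng.random(len(per_offs)) < amp
            for o in per_offs[hit]:
                genome[(mid + o) % L] = "A"
                genome[(mid + o + 1) % L] = "A"

    sequence = "".join(genome)
    replicon = Replicon(cfg.replicon_name, L, circular=cfg.circular, sequence=sequence)

    # --- MNase fragments and naked control --------------------------------
    flo, fhi = cfg.fragment_len_range
    mean_flen = (flo + fhi) / 2.0
    frags: list[Fragment] = []
    wrap_counter = 0
    for row in truth_dyads.itertuples():
        lam = cfg.depth * mu_at[row.midpoint % L] / mean_flen
        nf = int(rng.poisson(lam))
        centers = np.rint(row.midpoint + rng.normal(0, cfg.jitter_sd, nf)).astype(int)
        lens = rng.integers(flo, fhi + 1, nf)
        for c, fl in zip(centers, lens):
            wrap_counter = _add_fragment(frags, cfg, int(c), int(fl), wrap_counter)
    fragset = FragmentSet(replicon, frags)
    mnase = tio.fragments_to_coverage(fragset, "pileup")

    naked_frags: list[Fragment] = []
    n_naked = len(frags)
    centers = rng.integers(0, L, n_naked)
    lens = rng.integers(flo, fhi + 1, n_naked)
    for c, fl in zip(centers, lens):
        wrap_counter = _add_fragment(naked_frags, cfg, int(c), int(fl), wrap_counter)
    naked = tio.fragments_to_coverage(FragmentSet(replicon, naked_frags), "pileup")

    # --- RNA coverage ------------------------------------------------------
    rna_vals = np.zeros(L)
    units["rna_start"] = pd.NA
    units["rna_end"] = pd.NA
    units["level"] = 0.0
    rag = cfg.ragged_bp
    genes = units[~units.novel]
    for g, grp in genes.groupby("operon"):
        if not grp.expressed.iloc[0]:
            continue
        level = float(rng.lognormal(math.log(cfg.rna_depth), cfg.rna_sigma))
        s = int(grp.start.min()) + int(rng.integers(-rag, rag + 1))
        e = int(grp.end.max()) + int(rng.integers(-rag, rag + 1))
        rna_vals[s:e] = level
        units.loc[units.operon == g, ["rna_start", "rna_end", "level"]] = [s, e, level]
    for row in units[units.novel].itertuples():
        level = float(rng.lognormal(math.log(cfg.rna_depth), cfg.rna_sigma))
        s = row.start + int(rng.integers(-rag, rag + 1))
        e = row.end + int(rng.integers(-rag, rag + 1))
        rna_vals[s:e] = level
        units.loc[units.id == row.id, ["rna_start", "rna_end", "level"]] = [s, e, level]
    rna = CoverageTrack(replicon, rna_vals)

    if class_cycle:
        units["profile_class"] = [
            profile_class_of.get(int(g), 0) if not nv else 0
            for g, nv in zip(units.operon, units.novel)
        ]

    return SimBundle(cfg, replicon, annotations, fragset, mnase, naked, rna,
                     truth_dyads, units, genic_mask)


def _add_fragment(frags, cfg, center, flen, wrap_counter) -> int:
    L = cfg.genome_length
    s = center - flen // 2
    e = s + flen
    s_mod, e_mod = s % L, e % L
    if s // L == (e - 1) // L:  # no origin crossing
        frags.append(Fragment(cfg.replicon_name, s_mod, s_mod + flen))
    elif cfg.circular:
        wrap_counter += 1
        frags.append(Fragment(cfg.replicon_name, s_mod, L, wrap_id=wrap_counter))
        frags.append(Fragment(cfg.replicon_name, 0, e_mod, wrap_id=wrap_counter))
    return wrap_counter


# ---------------------------------------------------------------------------
# emission


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the plain-text formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "annotations": out / "annotations.gff3",
        "fragments": out / "fragments.bed",
        "mnase": out / "mnase.bedgraph",
        "naked": out / "naked.bedgraph",
        "rna": out / "rna.bedgraph",
        "truth_dyads": out / "truth_dyads.tsv",
        "truth_units": out / "truth_units.tsv",
        "config": out / "sim_config.txt",
    }
    tio.write_fasta([bundle.replicon], paths["genome"])
    tio.write_gff(bundle.annotations, paths["annotations"])
    tio.write_fragments_bed(bundle.fragments, paths["fragments"])
    tio.write_bedgraph(bundle.mnase, paths["mnase"])
    tio.write_bedgraph(bundle.naked, paths["naked"])
    tio.write_bedgraph(bundle.rna, paths["rna"])
    bundle.truth_dyads.to_csv(paths["truth_dyads"], sep="\t", index=False)
    bundle.truth_units.to_csv(paths["truth_units"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        for key, val in asdict(bundle.config).items():
            fh.write(f"{key} = {val}\n")
    return paths


# ---------------------------------------------------------------------------
# recovery scoring


def truth_compare(called, truth, tolerance: float, length: int | None = None,
                  circular: bool = True) -> dict:
    """Greedy 1-1 matching of called positions to planted positions.

    Returns recall, precision (None when nothing was called) and the mean
    absolute matched error.  Distances wrap on circular replicons when
    ``length`` is given.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    called = np.sort(np.asarray(called, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    if len(truth) == 0:
        raise ValueError("empty truth set")
    if len(called) == 0:
        return {"recall": 0.0, "precision": None, "mae": None,
                "n_truth": len(truth), "n_called": 0, "n_matched": 0}
    used = np.zeros(len(called), dtype=bool)
    errors = []
    for t in truth:
        j = np.searchsorted(called, t)
        best, best_d = None, None
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < len(called) and not used[cand]:
                d = abs(called[cand] - t)
                if circular and length:
                    d = min(d, length - d)
                if best_d is None or d < best_d:
                    best, best_d = cand, d
        if circular and length:  # wrap candidates at array ends
            for cand in (0, len(called) - 1):
                if not used[cand]:
                    d = abs(called[cand] - t)
                    d = min(d, length - d)
                    if d < (best_d if best_d is not None else np.inf):
                        best, best_d = cand, d
        if best is not None and best_d <= tolerance:
            used[best] = True
            errors.append(best_d)
    n_matched = len(errors)
    return {
        "recall": n_matched / len(truth),
        "precision": n_matched / len(called),
        "mae": float(np.mean(errors)) if errors else None,
        "n_truth": len(truth),
        "n_called": len(called),
        "n_matched": n_matched,
    }


def expected_refined_spans(truth_units: pd.DataFrame) -> pd.DataFrame:
    """Operon-level expressed spans the refinement should recover."""
    genes = truth_units[(~truth_units.novel) & truth_units.expressed]
    rows = []
    for g, grp in genes.groupby("operon"):
        rows.append(
            dict(operon=int(g), start=int(grp.start.min()), end=int(grp.end.max()),
                 strand=grp.strand.iloc[0], n_members=len(grp),
                 member_ids=tuple(sorted(grp.id)))
        )
    return pd.DataFrame(rows).sort_values("start").reset_index(drop=True)


def compare_units(units, truth_units: pd.DataFrame, boundary_tol: int = 20) -> dict:
    """Score refined transcript units against the planted transcriptome.

    Reports the fraction of expected boundaries recovered within
    ``boundary_tol`` bp, whether every planted operon merge was found (and
    only those), and novel-unit precision/recall (matched at >= 50%
    reciprocal overlap of the planted span).
    """
    expected = expected_refined_spans(truth_units)
    refined = [u for u in units if u.status != "novel"]
    novel = [u for u in units if u.status == "novel"]

    n_bounds = 0
    n_within = 0
    merges_expected = 0
    merges_found = 0
    spurious_merges = sum(
        1 for u in refined if u.status == "merged"
    )
    for row in expected.itertuples():
        best, best_ov = None, 0
        for u in refined:
            ov = min(u.end, row.end) - max(u.start, row.start)
            if ov > best_ov:
                best, best_ov = u, ov
        n_bounds += 2
        if best is not None:
            if abs(best.start - row.start) <= boundary_tol:
                n_within += 1
            if abs(best.end - row.end) <= boundary_tol:
                n_within += 1
        if row.n_members >= 2:
            merges_expected += 1
            if (best is not None and best.status == "merged"
                    and tuple(sorted(best.source_ids)) == row.member_ids):
                merges_found += 1
                spurious_merges -= 1
    truth_novel = truth_units[truth_units.novel]
    matched_novel = 0
    used = set()
    for row in truth_novel.itertuples():
        span = row.end - row.start
        for i, u in enumerate(novel):
            if i in used:
                continue
            ov = min(u.end, row.end) - max(u.start, row.start)
            if ov >= 0.5 * span:
                matched_novel += 1
                used.add(i)
                break
    return {
        "boundary_recovery": n_within / n_bounds if n_bounds else None,
        "merges_expected": merges_expected,
        "merges_found": merges_found,
        "spurious_merges": spurious_merges,
        "novel_recall": matched_novel / len(truth_novel) if len(truth_novel) else None,
        "novel_precision": matched_novel / len(novel) if novel else None,
        "n_expected_units": len(expected),
        "n_refined_units": len(refined),
    }


# ---------------------------------------------------------------------------
# lightweight window generator for the periodicity study


def simulate_dyad_windows(n: int, halfwidth: int = 30, gc: float = 0.65,
                          period: float | None = None, amplitude: float = 0.0,
                          seed: int = 0) -> DyadWindowSet:
    """i.i.d. dyad windows at a target GC, optionally with planted periodic
    AA dinucleotides every ``period`` bp at planting probability
    ``amplitude``.  Null windows (no period) calibrate the periodicity
    test; planted windows measure its power."""
    rng = np.random.default_rng(seed)
    width = 2 * halfwidth + 1
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.array(list("ACGT")), size=(n, width), p=p)
    if period is not None and amplitude > 0:
        per_offs = np.arange(0, width - 1, int(round(period)))
        hits = rng.random((n, len(per_offs))) < amplitude
        for i in range(n):
            for o in per_offs[hits[i]]:
                arr[i, o] = "A"
                arr[i, o + 1] = "A"
    windows = ["".join(row) for row in arr]
    return DyadWindowSet(halfwidth, windows, 0)
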