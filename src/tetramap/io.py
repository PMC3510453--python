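"""Readers and writers for the plain-text genomic formats the pipeline touches.

FASTA goes through Biopython; BED / bedGraph / GFF3 are simple tabular
formats handled directly.  All numbers written with repr-stable formatting
so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Annotation, CoverageTrack, Fragment, FragmentSet, Replicon, TranscriptUnit

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class CoordinateError(ValueError):
    """Raised when coordinates fall outside the replicon they reference."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular: bool | dict[str, bool] = True) -> list[Replicon]:
    """Read a genome FASTA into Replicon objects.

    ``circular`` may be a single flag for all records or a per-name mapping
    (the sidecar-config mechanism); unlisted names default to circular.
    """
    replicons: list[Replicon] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {rec.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        if isinstance(circular, dict):
            circ = circular.get(rec.id, True)
        else:
            circ = circular
        replicons.append(Replicon(rec.id, len(seq), circular=circ, sequence=seq))
    if not replicons:
        logger.warning("no FASTA records found in %s", path)
    names = [r.name for r in replicons]
    if len(set(names)) != len(names):
        raise FormatError("duplicate replicon names in FASTA")
    return replicons


def write_fasta(replicons: list[Replicon], path: str | Path, width: int = 70) -> None:
    records = []
    for rep in replicons:
        if rep.sequence is None:
            raise ValueError(f"replicon {rep.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(rep.sequence), id=rep.name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, replicons: list[Replicon]) -> dict[str, CoverageTrack]:
    """Expand a 4-column bedGraph into per-base coverage, one track per replicon.

    Uncovered bases are 0; overlapping intervals are summed.
    """
    by_name = {r.name: r for r in replicons}
    arrays = {name: np.zeros(r.length) for name, r in by_name.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            name, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if name not in by_name:
                raise CoordinateError(
                    f"{path}:{lineno}: unknown replicon {name!r}; known: {sorted(by_name)}"
                )
            if not (0 <= start < end <= by_name[name].length):
                raise CoordinateError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside replicon "
                    f"{name!r} of length {by_name[name].length}"
                )
            arrays[name][start:end] += value
    return {name: CoverageTrack(by_name[name], arr) for name, arr in arrays.items()}


def _fmt(v: float) -> str:
    """Compact stable float formatting (integers without trailing .0)."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_bedgraph(tracks, path: str | Path) -> None:
    """Write coverage/smoothed tracks as bedGraph, run-length compressing equal values.

    Zero runs are omitted (bedGraph convention: absent means 0).
    """
    if not isinstance(tracks, (list, tuple)):
        tracks = [tracks]
    with open(path, "w") as fh:
        for track in tracks:
            vals = np.asarray(track.values, dtype=float)
            n = len(vals)
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [n]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0.0:
                    fh.write(f"{track.replicon.name}\t{s}\t{e}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# BED fragments


def read_fragments_bed(path: str | Path, replicon: Replicon) -> FragmentSet:
    """Read protected fragments from BED3/6. Wrap pairs are encoded in the
    name column as ``wrap<id>a`` / ``wrap<id>b``."""
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            name, start, end = parts[0], int(parts[1]), int(parts[2])
            if name != replicon.name:
                raise CoordinateError(f"{path}:{lineno}: unknown replicon {name!r}")
            strand = parts[5] if len(parts) >= 6 else "."
            wrap_id = None
            if len(parts) >= 4 and parts[3].startswith("wrap"):
                wrap_id = int(parts[3][4:].rstrip("ab"))
            if not (0 <= start < end <= replicon.length):
                raise CoordinateError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside replicon"
                )
            frags.append(Fragment(name, start, end, strand, wrap_id))
    return FragmentSet(replicon, frags)


def write_fragments_bed(fragset: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(fragset.fragments):
            if f.wrap_id is not None:
                # two halves of one wrap pair share the id; suffix keeps names unique
                suffix = "a" if f.start == 0 else "b"
                name = f"wrap{f.wrap_id}{suffix}"
            else:
                name = f"frag{i}"
            fh.write(f"{fragset.replicon.name}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def fragments_to_coverage(fragset: FragmentSet, mode: str = "pileup") -> CoverageTrack:
    """Convert protected fragments to per-base coverage.

    pileup adds 1 over every covered base (protection signal); midpoint adds
    1 at floor((start+end-1)/2) only.  Wrap pairs are treated as one
    fragment on circular replicons: the pair's halves pile up where they
    lie, and the midpoint is computed on the unrolled fragment.
    """
    if mode not in ("pileup", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}; use 'pileup' or 'midpoint'")
    rep = fragset.replicon
    n = rep.length
    vals = np.zeros(n)
    # group wrap pairs
    wraps: dict[int, list[Fragment]] = {}
    plain: list[Fragment] = []
    for f in fragset.fragments:
        if f.wrap_id is not None:
            wraps.setdefault(f.wrap_id, []).append(f)
        else:
            plain.append(f)
    if mode == "pileup":
        for f in plain:
            vals[f.start : f.end] += 1
        for pair in wraps.values():
            for f in pair:
                vals[f.start : f.end] += 1
    else:
        for f in plain:
            vals[(f.start + f.end - 1) // 2] += 1
        for pair in wraps.values():
            # unroll: half B ends at origin (end == n), half A starts at 0
            tail = next(f for f in pair if f.end == n)
            head = next((f for f in pair if f.start == 0), None)
            length = (tail.end - tail.start) + (0 if head is None else head.end)
            mid = (tail.start + (tail.start + length - 1)) // 2 % n
            vals[mid] += 1
    return CoverageTrack(rep, vals)


# ---------------------------------------------------------------------------
# GFF3 annotations / refined units


def read_gff(path: str | Path, replicons: list[Replicon] | None = None) -> list[Annotation]:
    """Read gene annotations from GFF3 (1-based closed -> 0-based half-open)."""
    known = {r.name: r for r in replicons} if replicons else None
    anns: list[Annotation] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            name, _src, _type, start1, end1, _score, strand, _phase, attrs = parts
            if known is not None and name not in known:
                raise CoordinateError(f"{path}:{lineno}: unknown replicon {name!r}")
            ann_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    ann_id = kv[3:]
                    break
            if ann_id is None:
                auto += 1
                ann_id = f"ann{auto}"
            anns.append(Annotation(ann_id, name, int(start1) - 1, int(end1), strand))
    return anns


def write_gff(records, path: str | Path, source: str = "tetramap") -> None:
    """Write annotations or refined TranscriptUnits as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(records):
            if isinstance(rec, TranscriptUnit):
                attrs = f"ID=tu{i};status={rec.status}"
                if rec.source_ids:
                    attrs += ";source_ids=" + ",".join(rec.source_ids)
                attrs += f";mean_coverage={rec.mean_coverage:.3f}"
                ftype = "transcript"
                name, start, end, strand = rec.replicon_name, rec.start, rec.end, rec.strand
            else:
                attrs = f"ID={rec.id}"
                ftype = "gene"
                name, start, end, strand = rec.replicon_name, rec.start, rec.end, rec.strand
            fh.write(
                f"{name}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_units_gff(path: str | Path) -> list[TranscriptUnit]:
    """Read refined transcript units written by :func:`write_gff`."""
    units: list[TranscriptUnit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            units.append(
                TranscriptUnit(
                    parts[0],
                    int(parts[3]) - 1,
                    int(parts[4]),
                    parts[6],
                    attrs.get("status", "confirmed"),
                    tuple(attrs["source_ids"].split(",")) if "source_ids" in attrs else (),
                    float(attrs.get("mean_coverage", 0.0)),
                )
            )
    return units


# ---------------------------------------------------------------------------
# flat key-value config


def read_config(path: str | Path) -> dict[str, str]:
    """Read the flat ``key = value`` config format. Later keys win; CLI flags
    override config values at the CLI layer."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
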