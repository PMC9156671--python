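"""Readers and writers for the on-disk formats the pipeline touches.

One documented dialect per format:

* rGFA / GFA1 — ``S`` records with optional ``SN`` (origin sample),
  ``SO`` (origin offset) and ``SR`` (origin rank) tags, ``L`` records for
  oriented links.  Rank 0 marks the reference backbone; rank-0 segments of
  one chromosome must tile it contiguously.
* walk BED — six tab-separated columns ``chrom start end source sink path``
  where ``path`` is a ``>``/``<``-prefixed oriented segment list or ``.``
  for a missing walk (modeled on ``minigraph --call`` output).
* feature BED — five columns ``chrom start end name class``; GFF3 is also
  accepted and converted from 1-based closed to the internal 0-based
  half-open convention on read.
* depth TSV — four columns ``chrom window_start window_size mean_depth``
  with non-overlapping fixed-size windows.

All interval containers are 0-based half-open internally; the GFF3
conversion is the only coordinate shift in the codebase.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: sentinel for an absent haplotype walk ("." in the BED dialect)
MISSING = None

GFA_HEADER = "H\tVN:Z:1.0"

_ORIENTS = ("+", "-")


@dataclass
class Segment:
    """One rGFA segment: length, optional sequence and reference origin."""

    length: int
    sequence: Optional[str] = None
    origin_sample: str = ""
    origin_offset: int = 0
    origin_rank: int = 1

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("segment length must be non-negative")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with length field")


@dataclass
class PangenomeGraph:
    """Segments with reference-origin tags plus oriented links.

    ``segments`` maps segment id to :class:`Segment`; ``links`` is a set of
    ``(from_id, from_orient, to_id, to_orient)`` tuples.
    """

    segments: dict[str, Segment] = field(default_factory=dict)
    links: set[tuple[str, str, str, str]] = field(default_factory=set)

    def add_segment(self, sid: str, seg: Segment) -> None:
        if sid in self.segments:
            raise ValueError(f"duplicate segment id {sid!r}")
        self.segments[sid] = seg

    def add_link(self, a: str, ao: str, b: str, bo: str) -> None:
        for sid in (a, b):
            if sid not in self.segments:
                raise ValueError(f"link endpoint {sid!r} is not a segment")
        if ao not in _ORIENTS or bo not in _ORIENTS:
            raise ValueError("orientation must be '+' or '-'")
        self.links.add((a, ao, b, bo))

    def backbone(self, chrom: Optional[str] = None) -> list[str]:
        """Rank-0 segment ids sorted by (chromosome, origin offset)."""
        ids = [
            s
            for s, seg in self.segments.items()
            if seg.origin_rank == 0
            and (chrom is None or seg.origin_sample == chrom)
        ]
        ids.sort(key=lambda s: (self.segments[s].origin_sample,
                                self.segments[s].origin_offset))
        return ids

    def chromosomes(self) -> list[str]:
        return sorted({seg.origin_sample for seg in self.segments.values()
                       if seg.origin_rank == 0})

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for a, _, b, _ in self.links:
            if a not in self.segments or b not in self.segments:
                raise ValueError("link endpoint names a missing segment")
        for chrom in self.chromosomes():
            expect = None
            for sid in self.backbone(chrom):
                seg = self.segments[sid]
                if expect is not None and seg.origin_offset != expect:
                    raise ValueError(
                        f"rank-0 tiling broken on {chrom} at {sid} "
                        f"(offset {seg.origin_offset}, expected {expect})")
                expect = seg.origin_offset + seg.length


@dataclass
class WalkRecord:
    """One assembly's path through one bubble, in backbone coordinates."""

    assembly: str
    chrom: str
    ref_start: int
    ref_end: int
    path: Optional[tuple[tuple[str, str], ...]]  # ((seg, orient), ...) or MISSING

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"walk interval empty: {self.chrom}:{self.ref_start}-{self.ref_end}")
        if self.path is not None and len(self.path) == 0:
            raise ValueError("present path must be non-empty")

    @property
    def site_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.ref_start, self.ref_end)


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    name: str
    feature_class: str  # CDS, gene, satellite, telomere, gap, other

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("negative coordinate")
        if self.start >= self.end:
            raise ValueError(f"empty feature interval {self.chrom}:{self.start}-{self.end}")


class FeatureTrack:
    """A sortable collection of classed genomic intervals (0-based half-open)."""

    CLASSES = {"CDS", "gene", "satellite", "telomere", "gap", "other"}

    def __init__(self, records: Iterable[Feature] = ()):
        self.records: list[Feature] = sorted(records, key=lambda f: (f.chrom, f.start, f.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTrack) and self.records == other.records

    def of_class(self, cls: str) -> "FeatureTrack":
        return FeatureTrack(f for f in self.records if f.feature_class == cls)

    def on_chrom(self, chrom: str) -> "FeatureTrack":
        return FeatureTrack(f for f in self.records if f.chrom == chrom)


@dataclass(frozen=True)
class DepthWindow:
    chrom: str
    start: int
    size: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")
        if self.size <= 0:
            raise ValueError("window size must be positive")


class DepthTrack:
    """Fixed-size, non-overlapping windowed coverage along chromosomes."""

    def __init__(self, windows: Iterable[DepthWindow] = ()):
        self.windows: list[DepthWindow] = sorted(
            windows, key=lambda w: (w.chrom, w.start))
        sizes = {w.size for w in self.windows}
        if len(sizes) > 1:
            raise ValueError("all windows in one track must share a size")
        prev = None
        for w in self.windows:
            if prev and prev.chrom == w.chrom and w.start < prev.start + prev.size:
                raise ValueError("overlapping depth windows")
            prev = w

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def window_size(self) -> Optional[int]:
        return self.windows[0].size if self.windows else None


# ---------------------------------------------------------------------------
# rGFA


def _parse_tags(fields: Sequence[str]) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise ValueError(f"malformed tag {f!r}")
        tags[parts[0]] = parts[2]
    return tags


def read_rgfa(path) -> PangenomeGraph:
    """Parse an rGFA/GFA1 file into a :class:`PangenomeGraph`.

    Segments lacking an ``SR`` tag default to rank 1 (non-reference) with a
    warning.  Malformed lines raise :class:`ValueError` with the line number.
    """
    graph = PangenomeGraph()
    pending_links: list[tuple[int, tuple[str, str, str, str]]] = []
    missing_sr = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("H") or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fields[0] == "S":
                    if len(fields) < 3:
                        raise ValueError("S record needs id and sequence")
                    sid, seq = fields[1], fields[2]
                    tags = _parse_tags(fields[3:])
                    if seq == "*":
                        sequence = None
                        if "LN" not in tags:
                            raise ValueError("S record with '*' sequence needs LN tag")
                        length = int(tags["LN"])
                    else:
                        sequence = seq
                        length = int(tags.get("LN", len(seq)))
                    if "SR" not in tags:
                        missing_sr += 1
                    seg = Segment(
                        length=length,
                        sequence=sequence,
                        origin_sample=tags.get("SN", ""),
                        origin_offset=int(tags.get("SO", 0)),
                        origin_rank=int(tags["SR"]) if "SR" in tags else 1,
                    )
                    graph.add_segment(sid, seg)
                elif fields[0] == "L":
                    if len(fields) < 5:
                        raise ValueError("L record needs 5 fields")
                    pending_links.append(
                        (lineno, (fields[1], fields[2], fields[3], fields[4])))
                # other record types are ignored
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    for lineno, (a, ao, b, bo) in pending_links:
        try:
            graph.add_link(a, ao, b, bo)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    if missing_sr:
        warnings.warn(
            f"{missing_sr} segment(s) lacked an SR tag; defaulted to rank 1",
            stacklevel=2)
    graph.validate()
    return graph


def write_rgfa(graph: PangenomeGraph, path) -> None:
    """Write a valid GFA1 file with SN/SO/SR tags, deterministically ordered."""
    lines = [GFA_HEADER]
    for sid in sorted(graph.segments):
        seg = graph.segments[sid]
        seq = seg.sequence if seg.sequence is not None else "*"
        lines.append(
            f"S\t{sid}\t{seq}\tLN:i:{seg.length}"
            f"\tSN:Z:{seg.origin_sample}\tSO:i:{seg.origin_offset}"
            f"\tSR:i:{seg.origin_rank}")
    for a, ao, b, bo in sorted(graph.links):
        lines.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# walk BED

_PATH_RE = re.compile(r"([<>])([^<>]+)")


def parse_path(text: str) -> tuple[tuple[str, str], ...]:
    """Parse ``>s1>s2<s3`` into ``(("s1","+"), ("s2","+"), ("s3","-"))``."""
    steps = _PATH_RE.findall(text)
    if not steps or "".join(o + s for o, s in steps) != text:
        raise ValueError(f"malformed path string {text!r}")
    return tuple((sid, "+" if o == ">" else "-") for o, sid in steps)


def format_path(path: Sequence[tuple[str, str]]) -> str:
    return "".join((">" if o == "+" else "<") + sid for sid, o in path)


def read_walks(path, assembly: Optional[str] = None,
               permissive: bool = False) -> list[WalkRecord]:
    """Read a 6-column walk BED.

    ``assembly`` defaults to the file stem.  With ``permissive=True`` extra
    trailing columns (as real ``minigraph --call`` output may carry) are
    ignored instead of rejected.
    """
    label = assembly if assembly is not None else Path(path).stem
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6 and not (permissive and len(fields) > 6):
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, _source, _sink, pathstr = fields[:6]
            try:
                rec = WalkRecord(
                    assembly=label,
                    chrom=chrom,
                    ref_start=int(start),
                    ref_end=int(end),
                    path=MISSING if pathstr == "." else parse_path(pathstr),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_walks(records: Iterable[WalkRecord], path) -> None:
    lines = []
    for rec in records:
        pathstr = "." if rec.path is None else format_path(rec.path)
        source = rec.path[0][0] if rec.path else "."
        sink = rec.path[-1][0] if rec.path else "."
        lines.append(
            f"{rec.chrom}\t{rec.ref_start}\t{rec.ref_end}\t{source}\t{sink}\t{pathstr}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# features (BED / GFF3)


def _gff3_class(gff_type: str) -> str:
    if gff_type in FeatureTrack.CLASSES:
        return gff_type
    return {"CDS": "CDS", "gene": "gene"}.get(gff_type, "other")


def read_features(path, format: str = "BED") -> FeatureTrack:
    """Read a 5-column feature BED or a GFF3 file into a FeatureTrack.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open;
    this is the only coordinate conversion in the codebase.
    """
    if format not in ("BED", "GFF3"):
        raise ValueError(f"unknown format label {format!r}")
    feats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "BED":
                    if len(fields) < 3:
                        raise ValueError("BED needs at least 3 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"feat{lineno}"
                    cls = fields[4] if len(fields) > 4 else "other"
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                    cls = _gff3_class(fields[2])
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
                    name = attrs.get("ID", attrs.get("Name", f"feat{lineno}"))
                if cls not in FeatureTrack.CLASSES:
                    cls = "other"
                feats.append(Feature(chrom, start, end, name, cls))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return FeatureTrack(feats)


def write_features(track: FeatureTrack, path) -> None:
    lines = [f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{f.feature_class}"
             for f in track]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# depth TSV


def read_depth(path) -> DepthTrack:
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "start", "size", "depth"],
                     dtype={"chrom": str}, comment="#")
    return DepthTrack(
        DepthWindow(r.chrom, int(r.start), int(r.size), float(r.depth))
        for r in df.itertuples())


def write_depth(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for w in track:
            fh.write(f"{w.chrom}\t{w.start}\t{w.size}\t{w.mean_depth:.6g}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", names=["chrom", "length"],
                     dtype={"chrom": str})
    return dict(zip(df.chrom, df.length.astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
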