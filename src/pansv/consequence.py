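"""Coding consequences of structural variants against a gene model.

The coding length change of an SV is the net length difference
(alt − ref) restricted to the CDS-overlapping portion of the variant:
only the deleted bases that fall inside CDS count for deletions, and an
insertion contributes its full net gain only when its anchor interval
touches CDS.  Intronic ends of an SV are ignored.  A change divisible by 3
preserves the reading frame and shifts the protein by change/3 residues;
otherwise it is a frameshift.  In-frame copy-number changes of a tandem
motif extend (or contract) the protein by motif_length/3 residues per copy.

Copy number of a duplicated segment is estimated from windowed read depth
as round(mean depth over the region / baseline depth) − 1 additional
copies; the ±1 uncertainty inherent in depth ratios is exposed through the
raw ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .bubbles import SVRecord
from .graph_io import DepthTrack

KINDS = {"IN_FRAME_DEL", "IN_FRAME_INS", "FRAMESHIFT", "VNTR_EXTENSION",
         "GENE_SPANNING_DEL", "NON_CODING"}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]]  # 0-based half-open CDS intervals

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds)
        for s, e in self.cds:
            if s >= e:
                raise ValueError("empty CDS interval")

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds[0][0], self.cds[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class Consequence:
    kind: str
    aa_change: int = 0  # signed amino-acid count; 0 unless in-frame/VNTR
    genes: tuple[str, ...] = ()
    coding_bp_change: int = 0
    raw_ratio: float | None = None  # depth ratio, for copy-number estimates

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown consequence kind {self.kind!r}")
        if self.aa_change != 0 and self.kind not in (
                "IN_FRAME_DEL", "IN_FRAME_INS", "VNTR_EXTENSION"):
            raise ValueError("aa_change only applies to in-frame kinds")


def _cds_overlap_bp(start: int, end: int, gene: GeneModel) -> int:
    return sum(max(0, min(end, e) - max(start, s)) for s, e in gene.cds)


def coding_consequence(sv: SVRecord, gene: GeneModel) -> Consequence:
    """Classify one SV against one gene model.

    The amino-acid change magnitude is strand-independent; a deletion
    containing the gene's whole span is GENE_SPANNING_DEL regardless of
    frame arithmetic.
    """
    if sv.chrom != gene.chrom:
        raise ValueError("SV and gene are on different chromosomes")
    if gene.cds_length % 3 != 0:
        warnings.warn(
            f"CDS total of {gene.gene_id} not divisible by 3; proceeding")
    gs, ge = gene.span
    if sv.svtype == "DEL" and sv.start <= gs and sv.end >= ge:
        return Consequence(kind="GENE_SPANNING_DEL", genes=(gene.gene_id,))
    overlap = _cds_overlap_bp(sv.start, sv.end, gene)
    if overlap == 0:
        return Consequence(kind="NON_CODING", genes=(gene.gene_id,))
    if sv.alt_len >= sv.ref_len:
        # net insertion anchored inside CDS: full gain is coding
        change = sv.alt_len - sv.ref_len
    else:
        # deletion: only the removed bases inside CDS count
        net_loss = sv.ref_len - sv.alt_len
        change = -min(overlap, net_loss)
    if change == 0:
        return Consequence(kind="NON_CODING", genes=(gene.gene_id,),
                           coding_bp_change=0)
    if change % 3 != 0:
        return Consequence(kind="FRAMESHIFT", genes=(gene.gene_id,),
                           coding_bp_change=change)
    kind = "IN_FRAME_INS" if change > 0 else "IN_FRAME_DEL"
    return Consequence(kind=kind, aa_change=change // 3 if change > 0
                       else -((-change) // 3),
                       genes=(gene.gene_id,), coding_bp_change=change)


def vntr_extension(motif_len: int, extra_copies: int,
                   genes: Sequence[str] = ()) -> Consequence:
    """Protein-length effect of gaining/losing copies of a tandem motif.

    A motif length divisible by 3 gives an in-frame extension (or
    contraction for negative copies) of ``extra_copies × motif_len / 3``
    residues; any other motif length shifts the frame.
    """
    if motif_len <= 0:
        raise ValueError("motif length must be positive")
    if extra_copies == 0:
        return Consequence(kind="NON_CODING", genes=tuple(genes))
    bp = extra_copies * motif_len
    if motif_len % 3 != 0:
        return Consequence(kind="FRAMESHIFT", genes=tuple(genes),
                           coding_bp_change=bp)
    return Consequence(kind="VNTR_EXTENSION",
                       aa_change=bp // 3 if bp > 0 else -((-bp) // 3),
                       genes=tuple(genes), coding_bp_change=bp)


def copy_number_from_depth(depth: DepthTrack, region: tuple[str, int, int],
                           baseline_depth: float) -> int:
    """Additional copies of a region from windowed coverage.

    Uses windows fully contained in the region; the estimate is
    ``round(mean depth / baseline) − 1`` (ties away from zero), floored at
    0.  Scale-invariant in (depth, baseline).
    """
    if baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    chrom, start, end = region
    inside = [w.mean_depth for w in depth
              if w.chrom == chrom and w.start >= start and w.start + w.size <= end]
    if not inside:
        raise ValueError(
            "region contains no full depth window; use a smaller window size")
    ratio = (sum(inside) / len(inside)) / baseline_depth
    return max(0, int(math.floor(ratio + 0.5)) - 1)


def depth_ratio(depth: DepthTrack, region: tuple[str, int, int],
                baseline_depth: float) -> tuple[int, float]:
    """Copy-number estimate together with the raw depth ratio.

    Returns ``(additional_copies, mean_region_depth / baseline)``; the
    rounded estimate carries a ±1 uncertainty inherent to depth ratios.
    """
    if baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    chrom, start, end = region
    inside = [w.mean_depth for w in depth
              if w.chrom == chrom and w.start >= start and w.start + w.size <= end]
    if not inside:
        raise ValueError(
            "region contains no full depth window; use a smaller window size")
    ratio = (sum(inside) / len(inside)) / baseline_depth
    return max(0, int(math.floor(ratio + 0.5)) - 1), ratio
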