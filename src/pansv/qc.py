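"""Assembly completeness and correctness summaries.

Covers contiguity (NG50 against an expected genome size, PG50 on
haplotype-phased blocks), base accuracy (Phred-scaled QV from an externally
estimated error count), chromosome completeness (proximal centromeric
satellite and distal telomeric repeat content, with the end-to-end rule:
at least 50 kb of satellite at the proximal end and 500 bp of telomere at
the distal end, thresholds inclusive), and coverage dropout (maximal runs
of sub-threshold fixed-size depth windows).

Bovine autosomes are acrocentric, so "complete" here means
centromere-to-telomere; the proximal satellite window defaults to the
first 5 Mb and the distal telomere window to the last 10 kb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .graph_io import DepthTrack, FeatureTrack

SATELLITE_MIN_BP = 50_000
TELOMERE_MIN_BP = 500
PROXIMAL_WINDOW = 5_000_000
TELOMERE_WINDOW = 10_000
QV_CAP = 99.0


@dataclass
class ChromReport:
    chrom: str
    proximal_satellite_bp: int
    distal_telomere_bp: int
    n_gaps: int
    end_to_end: bool


def ng50(lengths, genome_size: int) -> int:
    """Smallest length L with total length of contigs ≥ L at least half the
    expected genome size; 0 (with a warning) if the assembly is too small."""
    if genome_size <= 0:
        raise ValueError("expected genome size must be positive")
    lens = sorted((int(x) for x in lengths), reverse=True)
    if not lens or any(x <= 0 for x in lens):
        raise ValueError("contig lengths must be positive and non-empty")
    half = genome_size / 2
    acc = 0
    for L in lens:
        acc += L
        if acc >= half:
            return L
    warnings.warn("assembly shorter than half the expected genome size; NG50=0")
    return 0


def pg50(phase_block_lengths, genome_size: int) -> int:
    """NG50 of haplotype-phased block lengths (contigs split at phase
    switches); always ≤ the contig NG50 of the same assembly."""
    return ng50(phase_block_lengths, genome_size)


def qv(error_bases: int, total_bases: int) -> float:
    """Phred-scaled base error rate, −10·log10(errors/total).

    Zero observed errors cap at 99 (the estimator saturates, not the
    assembly).
    """
    if total_bases <= 0:
        raise ValueError("total bases must be positive")
    if error_bases < 0 or error_bases > total_bases:
        raise ValueError("error bases must lie in [0, total]")
    if error_bases == 0:
        return QV_CAP
    return -10.0 * math.log10(error_bases / total_bases)


def qv_to_error_rate(phred: float) -> float:
    return 10 ** (-phred / 10.0)


def telomere_bases(repeats: FeatureTrack, chrom: str, chrom_length: int,
                   window: int = TELOMERE_WINDOW,
                   end: str = "distal") -> int:
    """Telomere-classed bases clipped to a terminal window of one chromosome.

    ``end`` selects the first (proximal) or last (distal) ``window`` bp.
    """
    if end not in ("proximal", "distal"):
        raise ValueError("end must be 'proximal' or 'distal'")
    lo, hi = (0, min(window, chrom_length)) if end == "proximal" \
        else (max(0, chrom_length - window), chrom_length)
    total = 0
    for f in repeats.of_class("telomere").on_chrom(chrom):
        total += max(0, min(f.end, hi) - max(f.start, lo))
    return total


def satellite_bases(repeats: FeatureTrack, chrom: str,
                    window: int = PROXIMAL_WINDOW) -> int:
    """Satellite-classed bases within the proximal window of one chromosome."""
    total = 0
    for f in repeats.of_class("satellite").on_chrom(chrom):
        total += max(0, min(f.end, window) - max(f.start, 0))
    return total


def end_to_end(satellites: FeatureTrack, telomeres: FeatureTrack,
               gaps: FeatureTrack, chrom: str, chrom_length: int,
               proximal_window: int = PROXIMAL_WINDOW,
               telomere_window: int = TELOMERE_WINDOW) -> ChromReport:
    """Per-chromosome completeness report with the inclusive 50 kb / 500 bp
    end-to-end rule."""
    sat = satellite_bases(satellites, chrom, proximal_window)
    tel = telomere_bases(telomeres, chrom, chrom_length,
                         telomere_window, "distal")
    n_gaps = len(gaps.of_class("gap").on_chrom(chrom))
    return ChromReport(
        chrom=chrom,
        proximal_satellite_bp=sat,
        distal_telomere_bp=tel,
        n_gaps=n_gaps,
        end_to_end=(sat >= SATELLITE_MIN_BP and tel >= TELOMERE_MIN_BP),
    )


def dropout_regions(depth: DepthTrack, threshold: float = 1.0) -> int:
    """Count maximal runs of consecutive windows below a coverage threshold.

    Windows are consecutive when adjacent on the same chromosome; each run
    counts as one dropout region.
    """
    count = 0
    prev = None  # (chrom, end) of last sub-threshold window
    for w in depth:
        if w.mean_depth < threshold:
            if prev is None or prev != (w.chrom, w.start):
                count += 1
            prev = (w.chrom, w.start + w.size)
        else:
            prev = None
    return count
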