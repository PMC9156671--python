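"""Match SV sets across pangenome replicates/platforms and score agreement.

Two SV records are considered the same site when they share chromosome and
type, their start positions differ by at most a breakpoint tolerance, and
their lengths agree within a ratio (min/max).  The defaults (100 bp, 0.9)
follow common SV-benchmarking practice and are recorded in every report.
Matching is greedy left-to-right and deterministic; an oracle test bounds
its cost relative to optimal bipartite matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .bubbles import SVRecord


@dataclass(frozen=True)
class MatchConfig:
    breakpoint_tolerance: int = 100
    length_ratio_min: float = 0.9

    def __post_init__(self) -> None:
        if self.breakpoint_tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not (0 < self.length_ratio_min <= 1):
            raise ValueError("length_ratio_min must be in (0, 1]")


@dataclass
class AgreementReport:
    n_truth: int
    n_test: int
    n_matched: int
    precision: float  # percent
    recall: float     # percent
    f1: float         # percent
    config: MatchConfig = field(default_factory=MatchConfig)

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth, "n_test": self.n_test,
            "n_matched": self.n_matched,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "breakpoint_tolerance": self.config.breakpoint_tolerance,
            "length_ratio_min": self.config.length_ratio_min,
        }


def _check_sorted(records: Sequence[SVRecord], name: str) -> None:
    keys = [(r.chrom, r.start) for r in records]
    if keys != sorted(keys):
        raise ValueError(f"{name} records must be sorted by (chrom, start)")


def records_match(a: SVRecord, b: SVRecord, config: MatchConfig) -> bool:
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    if abs(a.start - b.start) > config.breakpoint_tolerance:
        return False
    la, lb = a.length, b.length
    if max(la, lb) == 0:
        return True
    return min(la, lb) / max(la, lb) >= config.length_ratio_min


def match_sv_sets(test: Sequence[SVRecord], truth: Sequence[SVRecord],
                  config: MatchConfig = MatchConfig()) -> list[tuple[int, int]]:
    """Greedy left-to-right one-to-one matching.

    Returns (test index, truth index) pairs.  Each test record, scanned in
    sorted order, takes the earliest-start unmatched compatible truth
    record.  Inputs must be sorted by (chrom, start).
    """
    _check_sorted(test, "test")
    _check_sorted(truth, "truth")
    used = [False] * len(truth)
    pairs: list[tuple[int, int]] = []
    lo = 0
    for ti, trec in enumerate(test):
        # advance window start: truth records that can no longer match
        while lo < len(truth) and (
            truth[lo].chrom < trec.chrom
            or (truth[lo].chrom == trec.chrom
                and truth[lo].start < trec.start - config.breakpoint_tolerance)
        ):
            lo += 1
        j = lo
        while j < len(truth) and truth[j].chrom == trec.chrom \
                and truth[j].start <= trec.start + config.breakpoint_tolerance:
            if not used[j] and records_match(trec, truth[j], config):
                used[j] = True
                pairs.append((ti, j))
                break
            j += 1
    return pairs


def score_agreement(test: Sequence[SVRecord], truth: Sequence[SVRecord],
                    config: MatchConfig = MatchConfig()) -> AgreementReport:
    """Precision/recall/F1 (as percentages) of a test set against a truth set."""
    if len(truth) == 0:
        raise ValueError("empty truth set: recall undefined")
    matched = len(match_sv_sets(test, truth, config))
    precision = 100.0 * matched / len(test) if test else 0.0
    recall = 100.0 * matched / len(truth)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return AgreementReport(len(truth), len(test), matched,
                           precision, recall, f1, config)


@dataclass
class SharedFractions:
    labels: list[str]
    n_sites: int
    subset_counts: dict[frozenset, int]     # exact label subsets
    group_counts: dict[frozenset, int]      # subsets lifted to groups

    def fraction(self, subset: frozenset) -> float:
        return self.subset_counts.get(subset, 0) / self.n_sites

    @property
    def common_to_all(self) -> float:
        return self.subset_counts.get(frozenset(self.labels), 0) / self.n_sites \
            if self.n_sites else 0.0

    def unique_to(self, label: str) -> float:
        return self.subset_counts.get(frozenset([label]), 0) / self.n_sites \
            if self.n_sites else 0.0


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def shared_fractions(sv_sets: Mapping[str, Sequence[SVRecord]],
                     groups: Mapping[str, str] | None = None,
                     config: MatchConfig = MatchConfig()) -> SharedFractions:
    """Partition SVs from several call sets into sites and classify each
    site by which sets (and groups of sets, e.g. platforms) contain it.

    Cross-set pairwise matches are merged with union-find, so a site is a
    connected component of matched records; fractions are per site.
    """
    labels = list(sv_sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 SV sets")
    groups = dict(groups) if groups else {lab: lab for lab in labels}
    offsets: dict[str, int] = {}
    total = 0
    for lab in labels:
        offsets[lab] = total
        total += len(sv_sets[lab])
    uf = _UnionFind(total)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for ti, tj in match_sv_sets(sv_sets[la], sv_sets[lb], config):
                uf.union(offsets[la] + ti, offsets[lb] + tj)
    comp_labels: dict[int, set[str]] = {}
    for lab in labels:
        for k in range(len(sv_sets[lab])):
            root = uf.find(offsets[lab] + k)
            comp_labels.setdefault(root, set()).add(lab)
    subset_counts: dict[frozenset, int] = {}
    group_counts: dict[frozenset, int] = {}
    for labs in comp_labels.values():
        s = frozenset(labs)
        subset_counts[s] = subset_counts.get(s, 0) + 1
        g = frozenset(groups[lab] for lab in labs)
        group_counts[g] = group_counts.get(g, 0) + 1
    return SharedFractions(labels, len(comp_labels), subset_counts, group_counts)
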