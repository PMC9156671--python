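"""Pairwise discordance counts, UPGMA dendrograms, taurine-topology calls
and UpSet intersection sets from the allele matrix.

The distance between two assemblies is the number of mutually exclusive
bubbles: sites where both have a call and the calls differ.  Multi-allelic
differences count 1 per bubble.  Sites missing in either member of a pair
are skipped (pairwise-complete), so partially phased assemblies can be
compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .haplotypes import MISSING_IDX, AlleleMatrix


@dataclass
class DiscordanceMatrix:
    labels: list[str]
    D: np.ndarray              # symmetric counts (or rates if normalized)
    n_sites_used: np.ndarray   # per-pair jointly non-missing site counts

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.n_sites_used = np.asarray(self.n_sites_used, dtype=int)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape disagrees with labels")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")


def pairwise_discordance(matrix: AlleleMatrix,
                         restrict_chrom: Optional[str] = None,
                         normalize: bool = False) -> DiscordanceMatrix:
    """Count, for every assembly pair, the bubbles at which they took
    different paths.

    ``restrict_chrom`` limits the count to one chromosome.  With
    ``normalize=True`` counts are divided by the per-pair number of jointly
    non-missing sites (the raw count is the default).
    """
    ent = matrix.entries
    if restrict_chrom is not None:
        chroms = {k[0] for k in matrix.bubble_keys}
        if restrict_chrom not in chroms:
            raise ValueError(f"unknown chromosome {restrict_chrom!r}")
        mask = np.array([k[0] == restrict_chrom for k in matrix.bubble_keys])
        ent = ent[mask]
    present = ent != MISSING_IDX
    n = len(matrix.assemblies)
    D = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[:, i] & present[:, j]
            d = int(np.sum(both & (ent[:, i] != ent[:, j])))
            used[i, j] = used[j, i] = int(both.sum())
            D[i, j] = D[j, i] = d
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(used > 0, D / np.maximum(used, 1), 0.0)
    return DiscordanceMatrix(list(matrix.assemblies), D, used)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """UPGMA merge sequence over labeled leaves.

    ``merges`` lists ``(cluster_a, cluster_b, height)`` where clusters are
    scipy-style integer ids: leaves are 0..n-1 in label order, the k-th merge
    creates cluster n+k.  Heights are non-decreasing (ultrametricity).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def members(self) -> list[frozenset]:
        """Leaf-label set of every cluster id (leaves then merges)."""
        out = [frozenset([lab]) for lab in self.leaves]
        for a, b, _h in self.merges:
            out.append(out[a] | out[b])
        return out

    def clades(self) -> set[frozenset]:
        return set(self.members())

    def clade_heights(self) -> dict[frozenset, float]:
        mem = self.members()
        heights = {mem[i]: 0.0 for i in range(len(self.leaves))}
        for k, (a, b, h) in enumerate(self.merges):
            heights[mem[len(self.leaves) + k]] = h
        return heights

    def newick(self) -> str:
        n = len(self.leaves)
        reprs: dict[int, tuple[str, float]] = {
            i: (lab, 0.0) for i, lab in enumerate(self.leaves)}
        for k, (a, b, h) in enumerate(self.merges):
            (ra, ha), (rb, hb) = reprs[a], reprs[b]
            node = f"({ra}:{h - ha:g},{rb}:{h - hb:g})"
            reprs[n + k] = (node, h)
        return reprs[n + len(self.merges) - 1][0] + ";"


def upgma(dist: DiscordanceMatrix | np.ndarray,
          labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration with deterministic tie-breaks.

    At each step the pair at minimum distance is merged at half that
    distance; ties are broken by the lexicographically smallest pair of
    cluster minimum labels.  Accepts a DiscordanceMatrix or a plain
    symmetric matrix plus labels, so externally produced distances (e.g. a
    SNP distance matrix) can be fed in directly.
    """
    if isinstance(dist, DiscordanceMatrix):
        labels = dist.labels
        D = dist.D.copy().astype(float)
    else:
        D = np.asarray(dist, dtype=float).copy()
        if labels is None:
            raise ValueError("labels required with a plain matrix")
        labels = list(labels)
        if D.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape disagrees with labels")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")

    active: dict[int, dict] = {
        i: {"size": 1, "minlab": labels[i]} for i in range(n)}
    dmat: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = D[i, j]

    def get(a: int, b: int) -> float:
        return dmat[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        ids = sorted(active)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                d = get(a, b)
                lab = tuple(sorted((active[a]["minlab"], active[b]["minlab"])))
                key = (d, lab)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _lab), a, b = best
        sa, sb = active[a]["size"], active[b]["size"]
        new = {"size": sa + sb,
               "minlab": min(active[a]["minlab"], active[b]["minlab"])}
        for c in active:
            if c in (a, b):
                continue
            dac, dbc = get(a, c), get(b, c)
            dmat[(min(c, next_id), max(c, next_id))] = (sa * dac + sb * dbc) / (sa + sb)
        del active[a], active[b]
        active[next_id] = new
        merges.append((a, b, d / 2.0))
        next_id += 1
    return Dendrogram(list(labels), merges)


# ---------------------------------------------------------------------------
# topology classification


def classify_topology(tree: Dendrogram, outgroups: Sequence[str],
                      ingroup: Sequence[str]) -> str:
    """Classify a 5-leaf dendrogram by which ingroup member splits first.

    ``outgroups`` is ordered outermost-first (gaur then indicine in the
    bovine study); ``ingroup`` holds the three taurine labels.  Returns
    ``"<X>_OUT"`` where X is the ingroup label splitting first when the
    outgroup order holds, else ``"OTHER"``.
    """
    expected = set(outgroups) | set(ingroup)
    if len(outgroups) != 2 or len(ingroup) != 3 or len(expected) != 5:
        raise ValueError("need 2 ordered outgroups and 3 ingroup labels")
    if set(tree.leaves) != expected:
        raise ValueError(
            f"tree labels {sorted(tree.leaves)} do not match "
            f"{sorted(expected)}")
    clades = tree.clades()
    ing = frozenset(ingroup)
    # outermost outgroup splits first, second outgroup next
    if (ing | {outgroups[1]}) not in clades or ing not in clades:
        return "OTHER"
    for x in ingroup:
        if ing - {x} in clades:
            return f"{x}_OUT"
    return "OTHER"


# ---------------------------------------------------------------------------
# intersection sets


@dataclass
class IntersectionSets:
    """UpSet-style counts: per assembly subset S, the number of bubbles
    whose non-reference carriers are exactly S."""

    counts: dict[frozenset, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [(",".join(sorted(s)), c) for s, c in self.counts.items()]
        return sorted(rows, key=lambda r: (-r[1], r[0]))


def intersection_sets(matrix: AlleleMatrix) -> IntersectionSets:
    """Tally bubbles by the exact subset of assemblies carrying a
    non-reference allele.  Requires a complete matrix (run filter_complete
    first); all-reference bubbles contribute nothing."""
    if matrix.is_missing().any():
        raise ValueError("matrix has MISSING entries; run filter_complete first")
    counts: dict[frozenset, int] = {}
    for row in matrix.entries:
        s = frozenset(a for a, v in zip(matrix.assemblies, row) if v != 0)
        if s:
            counts[s] = counts.get(s, 0) + 1
    return IntersectionSets(counts)
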