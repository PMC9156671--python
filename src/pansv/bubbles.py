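"""Superbubble detection and SV typing on pangenome graphs.

A bubble is a source–sink subgraph whose alternative interior paths are the
alleles of one variant site.  Detection runs on the oriented-copy digraph
(each segment contributes a ``+`` and a ``-`` copy; every link induces the
edge and its reverse complement), and reports bubbles whose endpoints are
rank-0 forward segments, projected to backbone coordinates.

A reported bubble ``(s, t)`` satisfies, on the oriented digraph:

1. *reachability* — ``t`` is reachable from ``s``;
2. *matching* — the set of nodes reachable from ``s`` without passing
   through ``t`` equals the set of nodes that can reach ``t`` without
   passing through ``s``;
3. *acyclicity* — the induced subgraph on that set is a DAG;
4. it has at least two distinct source-to-sink allele paths;
5. every rank-0 interior node lies strictly between the endpoints on the
   backbone of the same chromosome;
6. *minimality* — no candidate shares its source with a sink interior to
   it, or its sink with a source interior to it;
7. *outermost* — its node set is not strictly contained in another
   surviving bubble's node set (bubbles are reported flat, not nested).

Nested variation inside a reported bubble is not re-decomposed, matching
minigraph's flat per-bubble calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .graph_io import PangenomeGraph

Node = tuple[str, str]  # (segment id, orientation)

SV_MIN_LEN = 50  # graph divergence threshold, reused for SV typing


@dataclass
class Bubble:
    chrom: str
    ref_start: int
    ref_end: int
    source_id: str
    sink_id: str
    alleles: list[tuple[Node, ...]]  # full source..sink paths; allele 0 = reference if present
    interior: set[str]
    allele_lengths: list[int]  # interior bp per allele
    has_ref: bool = True

    @property
    def site_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.ref_start, self.ref_end)

    @property
    def max_allele_length(self) -> int:
        return max(self.allele_lengths) if self.allele_lengths else 0

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class BubbleSummary:
    n_bubbles: int
    n_large: int  # bubbles with max allele length > 1 kb
    mean_bubble_size: float
    nonref_bases: int
    nonref_nodes: int


@dataclass
class SVRecord:
    """A backbone-projected structural variant."""

    chrom: str
    start: int
    end: int
    ref_len: int
    alt_len: int
    svtype: str  # INS, DEL, COMPLEX
    carriers: frozenset = field(default_factory=frozenset)
    flags: tuple = ()

    @property
    def site_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return max(self.ref_len, self.alt_len)


def sv_type(ref_len: int, alt_len: int) -> str:
    """Type an allele pair by the 50 bp divergence threshold."""
    if ref_len < SV_MIN_LEN and alt_len >= SV_MIN_LEN:
        return "INS"
    if alt_len < SV_MIN_LEN and ref_len >= SV_MIN_LEN:
        return "DEL"
    return "COMPLEX"


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def oriented_digraph(graph: PangenomeGraph) -> dict[Node, set[Node]]:
    """Adjacency of the oriented-copy digraph, including complement edges."""
    adj: dict[Node, set[Node]] = {}
    for sid in graph.segments:
        adj[(sid, "+")] = set()
        adj[(sid, "-")] = set()
    for a, ao, b, bo in graph.links:
        adj[(a, ao)].add((b, bo))
        adj[(b, _flip(bo))].add((a, _flip(ao)))
    return adj


def _reach_avoiding(adj: dict[Node, set[Node]], start: Node,
                    avoid: Node) -> set[Node]:
    """Nodes reachable from ``start`` along paths not passing through
    ``avoid`` as an intermediate; ``avoid`` itself is included if an edge
    reaches it.  ``start`` is always included."""
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        if v == avoid:
            continue  # do not expand past the avoided node
        for w in adj.get(v, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _is_dag(nodes: set[Node], adj: dict[Node, set[Node]], sink: Node) -> bool:
    """Acyclicity of the induced subgraph, not expanding past the sink."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {v: WHITE for v in nodes}

    def successors(v: Node):
        return iter(sorted(adj.get(v, ()))) if v != sink else iter(())

    for root in nodes:
        if color[root] != WHITE:
            continue
        color[root] = GRAY
        stack: list[tuple[Node, object]] = [(root, successors(root))]
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if w not in nodes:
                    continue
                if color[w] == GRAY:
                    return False
                if color[w] == WHITE:
                    color[w] = GRAY
                    stack.append((w, successors(w)))
                    advanced = True
                    break
            if not advanced:
                color[v] = BLACK
                stack.pop()
    return True


def _enumerate_paths(adj: dict[Node, set[Node]], nodes: set[Node],
                     source: Node, sink: Node,
                     cap: int = 4096) -> list[tuple[Node, ...]]:
    """All source→sink paths inside the (acyclic) node set, sorted."""
    paths: list[tuple[Node, ...]] = []
    stack: list[Node] = [source]

    def rec(v: Node) -> None:
        if len(paths) >= cap:
            raise RuntimeError("allele path explosion; graph too tangled")
        if v == sink:
            paths.append(tuple(stack))
            return
        for w in sorted(adj.get(v, ())):
            if w in nodes:
                stack.append(w)
                rec(w)
                stack.pop()

    rec(source)
    return sorted(paths)


class _Detector:
    def __init__(self, graph: PangenomeGraph):
        self.graph = graph
        self.adj = oriented_digraph(graph)
        self.radj: dict[Node, set[Node]] = {v: set() for v in self.adj}
        for v, ws in self.adj.items():
            for w in ws:
                self.radj[w].add(v)
        # backbone order per chromosome
        self.backbone: dict[str, list[str]] = {}
        self.pos: dict[str, tuple[str, int]] = {}  # sid -> (chrom, offset)
        for chrom in graph.chromosomes():
            ids = graph.backbone(chrom)
            self.backbone[chrom] = ids
            for sid in ids:
                self.pos[sid] = (chrom, graph.segments[sid].origin_offset)

    def is_candidate(self, s: str, t: str) -> Optional[dict]:
        """Check conditions 1–5 for the ordered rank-0 pair (s, t)."""
        if s == t:
            return None
        cs, ps = self.pos[s]
        ct, pt = self.pos[t]
        if cs != ct or ps >= pt:
            return None
        src, snk = (s, "+"), (t, "+")
        fwd = _reach_avoiding(self.adj, src, snk)
        if snk not in fwd:
            return None  # not reachable
        bwd = _reach_avoiding(self.radj, snk, src)
        if fwd != bwd:
            return None  # matching fails (escape or external entry)
        if not _is_dag(fwd, self.adj, snk):
            return None
        interior_nodes = fwd - {src, snk}
        # condition 5: rank-0 interior strictly between endpoints on backbone
        for sid, _o in interior_nodes:
            seg = self.graph.segments[sid]
            if seg.origin_rank == 0:
                if sid not in self.pos:
                    return None
                ci, pi = self.pos[sid]
                if ci != cs or not (ps < pi < pt):
                    return None
        try:
            paths = _enumerate_paths(self.adj, fwd, src, snk)
        except RuntimeError:
            return None
        if len(paths) < 2:
            return None
        return {"nodes": fwd, "interior": interior_nodes, "paths": paths}

    def detect(self) -> list[Bubble]:
        if not self.pos:
            raise ValueError("no reference backbone")
        found: list[tuple[str, str, dict]] = []
        for chrom, ids in self.backbone.items():
            for i, s in enumerate(ids):
                # skip provably redundant sources: single out-edge straight to
                # the adjacent backbone segment (minimality would drop any
                # candidate from here in favour of that successor)
                outs = self.adj[(s, "+")]
                if len(outs) == 1 and i + 1 < len(ids):
                    (nsid, no), = outs
                    if no == "+" and nsid == ids[i + 1]:
                        continue
                for t in ids[i + 1:]:
                    cand = self.is_candidate(s, t)
                    if cand is not None:
                        found.append((s, t, cand))
                        break  # minimal sink for this source
        # source-side minimality: drop (s, t) if an interior rank-0 node s'
        # yields a candidate (s', t)
        surviving = []
        for s, t, cand in found:
            dominated = False
            for sid, o in cand["interior"]:
                if o == "+" and self.graph.segments[sid].origin_rank == 0:
                    if self.is_candidate(sid, t) is not None:
                        dominated = True
                        break
            if not dominated:
                surviving.append((s, t, cand))
        # outermost: drop bubbles strictly contained in another's node set
        keep = []
        for i, (s, t, cand) in enumerate(surviving):
            contained = any(
                j != i and cand["nodes"] < other[2]["nodes"]
                for j, other in enumerate(surviving))
            if not contained:
                keep.append((s, t, cand))
        return sorted((self._to_bubble(s, t, c) for s, t, c in keep),
                      key=lambda b: (b.chrom, b.ref_start, b.ref_end))

    def _to_bubble(self, s: str, t: str, cand: dict) -> Bubble:
        segs = self.graph.segments
        chrom, _ = self.pos[s]
        ref_start = segs[s].origin_offset + segs[s].length
        ref_end = segs[t].origin_offset

        def interior_len(path) -> int:
            return sum(segs[sid].length for sid, _o in path[1:-1])

        def is_ref(path) -> bool:
            inner = path[1:-1]
            if any(o != "+" or segs[sid].origin_rank != 0 for sid, o in inner):
                return False
            offs = [segs[sid].origin_offset for sid, _o in inner]
            # reference path tiles [ref_start, ref_end)
            expect = ref_start
            for sid, _o in inner:
                if segs[sid].origin_offset != expect:
                    return False
                expect += segs[sid].length
            return expect == ref_end

        paths = cand["paths"]
        ref_paths = [p for p in paths if is_ref(p)]
        if ref_paths:
            ordered = [ref_paths[0]] + sorted(p for p in paths if p != ref_paths[0])
            has_ref = True
        else:
            ordered = sorted(paths)
            has_ref = False
        return Bubble(
            chrom=chrom,
            ref_start=ref_start,
            ref_end=ref_end,
            source_id=s,
            sink_id=t,
            alleles=ordered,
            interior={sid for sid, _o in cand["interior"]},
            allele_lengths=[interior_len(p) for p in ordered],
            has_ref=has_ref,
        )


def detect_superbubbles(graph: PangenomeGraph) -> list[Bubble]:
    """Enumerate outermost minimal superbubbles with rank-0 endpoints.

    Raises ``ValueError("no reference backbone")`` on a graph without rank-0
    segments.  Output is sorted by (chrom, ref_start).
    """
    return _Detector(graph).detect()


def summarize_bubbles(bubbles: list[Bubble],
                      graph: PangenomeGraph) -> BubbleSummary:
    """Aggregate counts: large (>1 kb) bubbles, mean size, non-reference
    sequence content of the graph."""
    sizes = [b.max_allele_length for b in bubbles]
    nonref = [seg for seg in graph.segments.values() if seg.origin_rank > 0]
    return BubbleSummary(
        n_bubbles=len(bubbles),
        n_large=sum(1 for s in sizes if s > 1000),
        mean_bubble_size=(sum(sizes) / len(sizes)) if sizes else 0.0,
        nonref_bases=sum(seg.length for seg in nonref),
        nonref_nodes=len(nonref),
    )


def classify_sv(bubble: Bubble, allele: int = 1) -> SVRecord:
    """Type one non-reference allele of a bubble as INS/DEL/COMPLEX.

    ``allele`` indexes into the bubble's allele list and must not be the
    reference allele.  A bubble without a reference allele is typed COMPLEX
    and flagged ``no-ref``.
    """
    if len(bubble.alleles) < 2:
        raise ValueError("bubble must have at least 2 alleles")
    if not bubble.has_ref:
        return SVRecord(
            chrom=bubble.chrom, start=bubble.ref_start, end=bubble.ref_end,
            ref_len=bubble.ref_length,
            alt_len=bubble.allele_lengths[allele],
            svtype="COMPLEX", flags=("no-ref",))
    if allele == 0:
        raise ValueError("allele 0 is the reference allele")
    ref_len = bubble.ref_length
    alt_len = bubble.allele_lengths[allele]
    return SVRecord(
        chrom=bubble.chrom, start=bubble.ref_start, end=bubble.ref_end,
        ref_len=ref_len, alt_len=alt_len, svtype=sv_type(ref_len, alt_len))


def classify_all(bubble: Bubble) -> list[SVRecord]:
    """One SVRecord per non-reference allele of a bubble."""
    if not bubble.has_ref:
        return [classify_sv(bubble)]
    return [classify_sv(bubble, a) for a in range(1, len(bubble.alleles))]
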