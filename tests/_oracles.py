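"""Independent brute-force oracles and random-input generators.

Everything here is deliberately naive (exhaustive enumeration, triple
loops, per-base counting) so it can serve as ground truth for the
efficient implementations.
"""

from __future__ import annotations

import numpy as np

from pansv.graph_io import PangenomeGraph, Segment


# ---------------------------------------------------------------------------
# random graphs


def random_graph(rng: np.random.Generator, max_segments: int = 12) -> PangenomeGraph:
    """A random rGFA-style graph: a rank-0 backbone chain plus random
    rank-1 nodes, skip edges, dangling nodes and occasional reverse links."""
    g = PangenomeGraph()
    n0 = int(rng.integers(2, 7))
    offset = 0
    backbone = []
    for i in range(n0):
        length = int(rng.integers(1, 200))
        sid = f"s{i}"
        g.add_segment(sid, Segment(length=length, origin_sample="c1",
                                   origin_offset=offset, origin_rank=0))
        offset += length
        backbone.append(sid)
    for a, b in zip(backbone, backbone[1:]):
        g.add_link(a, "+", b, "+")
    n1 = int(rng.integers(0, max_segments - n0 + 1))
    alt_ids = []
    for k in range(n1):
        aid = f"a{k}"
        g.add_segment(aid, Segment(length=int(rng.integers(1, 500)),
                                   origin_sample="x", origin_rank=1))
        alt_ids.append(aid)
        i = int(rng.integers(0, n0))
        g.add_link(backbone[i], "+", aid, "+")
        r = rng.random()
        if r < 0.75:  # out-edge to a random backbone node (may go backwards)
            j = int(rng.integers(0, n0))
            g.add_link(aid, "+", backbone[j], "+")
        elif r < 0.85 and alt_ids[:-1]:
            other = alt_ids[int(rng.integers(0, len(alt_ids) - 1))]
            g.add_link(aid, "+", other, "+")
        elif r < 0.92:
            j = int(rng.integers(0, n0))
            g.add_link(aid, "-", backbone[j], "+")  # reverse attachment
        # else: dangling tip
    # deletion-style skip edges
    for _ in range(int(rng.integers(0, 3))):
        i = int(rng.integers(0, n0 - 1))
        j = int(rng.integers(i + 1, n0))
        g.add_link(backbone[i], "+", backbone[j], "+")
    if rng.random() < 0.1 and n0 > 2:  # occasionally break the chain
        i = int(rng.integers(0, n0 - 1))
        g.links.discard((backbone[i], "+", backbone[i + 1], "+"))
    return g


# ---------------------------------------------------------------------------
# exhaustive superbubble oracle


def _adjacency(graph: PangenomeGraph):
    flip = {"+": "-", "-": "+"}
    adj: dict[tuple, set] = {}
    radj: dict[tuple, set] = {}
    for sid in graph.segments:
        for o in "+-":
            adj[(sid, o)] = set()
            radj[(sid, o)] = set()
    for a, ao, b, bo in graph.links:
        adj[(a, ao)].add((b, bo))
        adj[(b, flip[bo])].add((a, flip[ao]))
    for v, ws in adj.items():
        for w in ws:
            radj[w].add(v)
    return adj, radj


def _exhaustive_reach(adj, start, avoid):
    """Nodes on simple paths from start that do not pass through avoid as an
    intermediate (avoid itself is collected when an edge reaches it)."""
    seen = {start}

    def rec(v, visited):
        for w in adj.get(v, ()):
            seen.add(w)
            if w == avoid or w in visited:
                continue
            rec(w, visited | {w})

    rec(start, {start})
    return seen


def _exhaustive_paths(adj, nodes, source, sink):
    paths = []

    def rec(v, path):
        if v == sink:
            paths.append(tuple(path))
            return
        for w in sorted(adj.get(v, ())):
            if w in nodes and w not in path:
                rec(w, path + [w])

    rec(source, [source])
    return sorted(paths)


def _has_cycle(adj, nodes, sink):
    # exhaustive: a cycle exists iff some node can reach itself without
    # expanding past the sink
    for v in nodes:
        stack = [(v, {v})]
        while stack:
            u, visited = stack.pop()
            if u == sink:
                continue
            for w in adj.get(u, ()):
                if w not in nodes:
                    continue
                if w == v:
                    return True
                if w not in visited:
                    stack.append((w, visited | {w}))
    return False


def brute_force_superbubbles(graph: PangenomeGraph):
    """Test every ordered rank-0 forward pair against the superbubble
    definition by exhaustive path enumeration; then apply minimality and
    outermost filtering.  Returns [(source, sink, allele paths)] sorted by
    backbone position."""
    adj, radj = _adjacency(graph)
    rank0 = [(sid, seg.origin_sample, seg.origin_offset)
             for sid, seg in graph.segments.items() if seg.origin_rank == 0]
    rank0.sort(key=lambda x: (x[1], x[2]))
    pos = {sid: (chrom, off) for sid, chrom, off in rank0}

    candidates = {}
    for s, cs, ps in rank0:
        for t, ct, pt in rank0:
            if cs != ct or ps >= pt:
                continue
            src, snk = (s, "+"), (t, "+")
            fwd = _exhaustive_reach(adj, src, snk)
            if snk not in fwd:
                continue
            bwd = _exhaustive_reach(radj, snk, src)
            if fwd != bwd:
                continue
            if _has_cycle(adj, fwd, snk):
                continue
            interior = fwd - {src, snk}
            ok = True
            for sid, _o in interior:
                if graph.segments[sid].origin_rank == 0:
                    ci, pi = pos[sid]
                    if ci != cs or not (ps < pi < pt):
                        ok = False
                        break
            if not ok:
                continue
            paths = _exhaustive_paths(adj, fwd, src, snk)
            if len(paths) < 2:
                continue
            candidates[(s, t)] = {"nodes": fwd, "interior": interior,
                                  "paths": paths}

    def minimal(st):
        s, t = st
        interior = candidates[st]["interior"]
        for (s2, t2) in candidates:
            if s2 == s and (t2, "+") in interior:
                return False
            if t2 == t and (s2, "+") in interior:
                return False
        return True

    survivors = {st: c for st, c in candidates.items() if minimal(st)}
    keep = []
    for st, c in survivors.items():
        if not any(o != st and c["nodes"] < oc["nodes"]
                   for o, oc in survivors.items()):
            keep.append((st[0], st[1], c["paths"]))
    keep.sort(key=lambda x: (pos[x[0]][0], pos[x[0]][1]))
    return keep


# ---------------------------------------------------------------------------
# interval overlap oracle


def all_pairs_overlap(bubbles, cds):
    """O(n*m) overlap pair count and per-pair bp, half-open intervals."""
    pairs = []
    for (bc, bs, be) in bubbles:
        for f in cds:
            if f.chrom == bc:
                ov = min(be, f.end) - max(bs, f.start)
                if ov > 0:
                    pairs.append(((bc, bs, be), f.name, ov))
    return pairs


# ---------------------------------------------------------------------------
# discordance oracle


def triple_loop_discordance(entries, missing=-1):
    """D[i,j] by looping over sites for every pair."""
    n_sites, n_asm = entries.shape
    D = np.zeros((n_asm, n_asm), dtype=int)
    for i in range(n_asm):
        for j in range(n_asm):
            if i == j:
                continue
            d = 0
            for k in range(n_sites):
                a, b = entries[k, i], entries[k, j]
                if a != missing and b != missing and a != b:
                    d += 1
            D[i, j] = d
    return D


# ---------------------------------------------------------------------------
# rooted 5-leaf topology enumeration


def all_rooted_topologies(leaves):
    """All (2n-3)!! rooted binary labeled topologies as nested tuples."""
    leaves = list(leaves)

    def trees(s):
        if len(s) == 1:
            yield s[0]
            return
        first, rest = s[0], s[1:]
        for mask in range(2 ** len(rest)):
            left = [first] + [x for i, x in enumerate(rest) if mask >> i & 1]
            right = [x for i, x in enumerate(rest) if not mask >> i & 1]
            if not right:
                continue
            for tl in trees(left):
                for tr in trees(right):
                    yield (tl, tr)

    return list(trees(leaves))


def nested_clades(tree) -> set[frozenset]:
    out = set()

    def rec(node) -> frozenset:
        if isinstance(node, str):
            c = frozenset([node])
        else:
            c = rec(node[0]) | rec(node[1])
        out.add(c)
        return c

    rec(tree)
    return out
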