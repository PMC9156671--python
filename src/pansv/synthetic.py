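"""Planted-truth pangenome simulator.

Generates, from a seed and config, everything the downstream analyses
consume: a rooted ultrametric tree over the haplotype assemblies, a
catalogue of structural variants (insertions, deletions and VNTR
expansions, all ≥50 bp) planted on the tree's branches so that every SV's
carrier set is exactly a clade, a minigraph-style pangenome graph built by
splitting the backbone at SV breakpoints and attaching allele nodes,
per-assembly haplotype-walk files, gene/repeat/gap annotation tracks, and
windowed depth tracks carrying planted copy-number signal.

The default configuration mirrors the bovine study conditions at desk
scale: five haplotypes (three taurine — O, B, P — plus indicine N and gaur
G as increasingly distant outgroups), two 5 Mb chromosomes, and an SV rate
giving roughly 300 events, enough to make the planted tree topology
recoverable from SV discordance alone.

Emulated features of real pangenomes and their limits:

* bubbles are flat and bi-allelic per branch (no nested variation);
* insertion bubbles keep a 1 bp reference anchor segment so every bubble
  projects to a non-empty backbone interval;
* graph order-sensitivity is abstracted by :func:`emit_replicates`, which
  drops or splits each bubble independently with a noise probability —
  the real mechanism (alignment of palindromic sequence) is not modeled;
* depth is a multiplicative-noise model with an exponentially rare
  dropout process, not read placement.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import yaml

from .bubbles import SVRecord, sv_type
from .graph_io import (
    DepthTrack, DepthWindow, Feature, FeatureTrack, PangenomeGraph, Segment,
    WalkRecord, write_chrom_sizes, write_depth, write_features, write_rgfa,
    write_walks,
)
from .haplotypes import AlleleMatrix

DEFAULT_TREE = "((((P:1,B:1):2,O:3):5,N:8):12,G:20);"


@dataclass
class SimConfig:
    """Study conditions for one synthetic pangenome."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    leaves: tuple = ("O", "B", "P", "N", "G")
    tree_newick: str = DEFAULT_TREE
    root_edge_length: float = 2.0     # branch above the root: SVs shared by all
    sv_rate: float = 6e-7             # events / bp / unit branch length
    sv_len_mean: float = 500.0        # geometric, minimum 50 bp
    vntr_fraction: float = 0.15
    n_genes: int = 100
    cds_per_gene: int = 4
    cds_length: int = 150             # per exon; 4 x 150 keeps genes in frame
    intron_length: int = 300
    gene_placement: str = "avoid"     # "avoid" (planted depletion) or "independent"
    p_satellite: float = 0.8          # per-chromosome proximal completeness
    p_telomere: float = 0.6           # per-chromosome distal completeness
    depth_mean: float = 25.0
    depth_window: int = 10_000
    depth_noise_cv: float = 0.05      # multiplicative window noise
    n_cnvs: int = 1
    cnv_extra_copies: int = 4
    cnv_length: int = 100_000
    homoplasy_rate: float = 0.0       # fraction of SVs with non-clade carriers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("counts must be positive")
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("leaf labels must be unique")
        if self.sv_len_mean < 50:
            raise ValueError("mean SV length below the 50 bp divergence threshold")
        if self.gene_placement not in ("avoid", "independent"):
            raise ValueError("gene_placement must be 'avoid' or 'independent'")

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def genome_size(self) -> int:
        return self.n_chroms * self.chrom_length

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(
                f"unknown config key(s) {sorted(bad)}; valid keys: {sorted(known)}")
        if "leaves" in data:
            data["leaves"] = tuple(data["leaves"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["leaves"] = list(self.leaves)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class PlantedCNV:
    chrom: str
    start: int
    end: int
    extra_copies: int
    carriers: frozenset


@dataclass
class SyntheticTruth:
    """Planted tree, SV catalogue and all derived tracks."""

    config: SimConfig
    tree_newick: str
    branches: list[tuple[str, float, frozenset]]  # (branch id, length, clade)
    sv_catalogue: list[SVRecord]
    sv_branch: list[str]                          # originating branch per SV
    sv_alt_detail: list[dict]                     # motif/copies for VNTRs
    chrom_sizes: dict[str, int]
    graph: PangenomeGraph
    walks: dict[str, list[WalkRecord]]
    gene_track: FeatureTrack
    repeat_tracks: dict[str, FeatureTrack]
    gap_tracks: dict[str, FeatureTrack]
    depth_tracks: dict[str, DepthTrack]
    cnvs: list[PlantedCNV]
    contigs: dict[str, list[int]]
    phase_blocks: dict[str, list[int]]
    assembly_stats: dict[str, dict] = field(default_factory=dict)

    @property
    def carrier_sets(self) -> dict[tuple, frozenset]:
        return {sv.site_key: sv.carriers for sv in self.sv_catalogue}

    def carrier_matrix(self) -> AlleleMatrix:
        """The planted allele matrix: 1 where a leaf carries the SV, else 0."""
        leaves = list(self.config.leaves)
        ent = np.zeros((len(self.sv_catalogue), len(leaves)), dtype=int)
        for i, sv in enumerate(self.sv_catalogue):
            for j, leaf in enumerate(leaves):
                if leaf in sv.carriers:
                    ent[i, j] = 1
        return AlleleMatrix([sv.site_key for sv in self.sv_catalogue],
                            leaves, ent)

    def emit(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        write_rgfa(self.graph, out / "graph.gfa")
        write_chrom_sizes(self.chrom_sizes, out / "chrom_sizes.tsv")
        (out / "tree.nwk").write_text(self.tree_newick + "\n")
        walkdir = out / "walks"
        walkdir.mkdir(exist_ok=True)
        for leaf, recs in self.walks.items():
            write_walks(recs, walkdir / f"{leaf}.bed")
        write_features(self.gene_track, out / "genes.bed")
        for leaf in self.config.leaves:
            write_features(self.repeat_tracks[leaf], out / f"repeats_{leaf}.bed")
            write_features(self.gap_tracks[leaf], out / f"gaps_{leaf}.bed")
            write_depth(self.depth_tracks[leaf], out / f"depth_{leaf}.tsv")
        with open(out / "truth_svs.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tref_len\talt_len\tsvtype\tbranch\tcarriers\n")
            for sv, br in zip(self.sv_catalogue, self.sv_branch):
                fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.ref_len}\t"
                         f"{sv.alt_len}\t{sv.svtype}\t{br}\t"
                         f"{','.join(sorted(sv.carriers))}\n")
        with open(out / "lengths.tsv", "w") as fh:
            for leaf, lens in self.contigs.items():
                for i, L in enumerate(lens):
                    fh.write(f"{leaf}\tcontig{i}\t{L}\n")
        with open(out / "blocks.tsv", "w") as fh:
            for leaf, lens in self.phase_blocks.items():
                for i, L in enumerate(lens):
                    fh.write(f"{leaf}\tblock{i}\t{L}\n")
        with open(out / "stats.tsv", "w") as fh:
            fh.write("assembly\ttotal_bases\terror_bases\n")
            for leaf, st in self.assembly_stats.items():
                fh.write(f"{leaf}\t{st['total_bases']}\t{st['error_bases']}\n")


# ---------------------------------------------------------------------------
# tree handling


def tree_branches(newick: str, leaves: tuple,
                  root_edge_length: float) -> list[tuple[str, float, frozenset]]:
    """Branches of a rooted Newick tree as (id, length, clade-below).

    The optional root edge (divergence from the graph backbone) carries SVs
    shared by every assembly.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    found = {t.label for t in tree.taxon_namespace}
    if found != set(leaves):
        raise ValueError(f"tree leaves {sorted(found)} != config leaves "
                         f"{sorted(leaves)}")
    branches = []
    for i, edge in enumerate(tree.preorder_edge_iter()):
        if edge.head_node is tree.seed_node:
            continue  # handled via root_edge_length
        clade = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter())
        length = edge.length if edge.length is not None else 0.0
        if length > 0:
            branches.append((f"b{i}_{'.'.join(sorted(clade))}", float(length), clade))
    if root_edge_length > 0:
        branches.append(("root", float(root_edge_length), frozenset(leaves)))
    return branches


# ---------------------------------------------------------------------------
# SV catalogue


def _shifted_geometric(rng: np.random.Generator, mean: float, minimum: int = 50) -> int:
    # geometric on {1,2,...} shifted so the minimum is `minimum` and the mean is `mean`
    p = 1.0 / (mean - minimum + 1)
    return minimum - 1 + int(rng.geometric(p))


_MOTIFS_IN_FRAME = [m for m in range(6, 91) if m % 3 == 0]
_MOTIFS_OFF_FRAME = [m for m in range(6, 91) if m % 3 != 0]


class _Occupancy:
    """Sorted non-overlapping footprints with a minimum 2 bp separation."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def fits(self, start: int, end: int) -> bool:
        i = bisect.bisect_left(self.starts, start)
        if i > 0 and self.ends[i - 1] + 2 > start:
            return False
        if i < len(self.starts) and end + 2 > self.starts[i]:
            return False
        return True

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def draw_catalogue(config: SimConfig, rng: np.random.Generator
                   ) -> tuple[list[SVRecord], list[str], list[dict]]:
    """Draw the planted SV catalogue (no graph construction).

    Per-branch event counts are Poisson(sv_rate × branch length × genome
    size); footprints are uniform on each chromosome with a minimum 2 bp
    separation so every SV becomes its own bubble.  Raises if a chromosome
    is too crowded to place an event after bounded retries.
    """
    branches = tree_branches(config.tree_newick, config.leaves,
                             config.root_edge_length)
    occupancy = {c: _Occupancy() for c in config.chroms}
    svs: list[SVRecord] = []
    origins: list[str] = []
    details: list[dict] = []
    for bid, length, clade in branches:
        n = int(rng.poisson(config.sv_rate * length * config.genome_size))
        for _ in range(n):
            if config.homoplasy_rate > 0 and rng.random() < config.homoplasy_rate:
                k = int(rng.integers(1, len(config.leaves) + 1))
                carriers = frozenset(
                    rng.choice(config.leaves, size=k, replace=False).tolist())
            else:
                carriers = clade
            detail: dict = {}
            if rng.random() < config.vntr_fraction:
                motifs = _MOTIFS_IN_FRAME if rng.random() < 0.5 else _MOTIFS_OFF_FRAME
                motif = int(rng.choice(motifs))
                extra = int(rng.integers(1, 9))
                extra = max(extra, math.ceil(50 / motif))
                ref_len, alt_len = motif, motif * (1 + extra)
                detail = {"kind": "VNTR", "motif_len": motif,
                          "extra_copies": extra}
            elif rng.random() < 0.5:
                alt = _shifted_geometric(rng, config.sv_len_mean)
                ref_len, alt_len = 1, alt            # insertion with 1 bp anchor
                detail = {"kind": "INS"}
            else:
                ref = _shifted_geometric(rng, config.sv_len_mean)
                ref_len, alt_len = ref, 0            # deletion
                detail = {"kind": "DEL"}
            chrom = config.chroms[int(rng.integers(0, config.n_chroms))]
            placed = False
            for _try in range(100):
                lo, hi = 2, config.chrom_length - ref_len - 2
                if hi <= lo:
                    break
                start = int(rng.integers(lo, hi))
                if occupancy[chrom].fits(start, start + ref_len):
                    occupancy[chrom].add(start, start + ref_len)
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "could not place an SV after 100 tries; chromosome "
                    "overcrowded — lower sv_rate or raise chrom_length")
            svs.append(SVRecord(
                chrom=chrom, start=start, end=start + ref_len,
                ref_len=ref_len, alt_len=alt_len,
                svtype=sv_type(ref_len, alt_len), carriers=carriers))
            origins.append(bid)
            details.append(detail)
    order = sorted(range(len(svs)),
                   key=lambda i: (svs[i].chrom, svs[i].start))
    return ([svs[i] for i in order], [origins[i] for i in order],
            [details[i] for i in order])


# ---------------------------------------------------------------------------
# graph and walks


def build_graph_and_walks(svs: list[SVRecord], chrom_sizes: dict[str, int],
                          leaves: tuple
                          ) -> tuple[PangenomeGraph, dict[str, list[WalkRecord]]]:
    """Split the backbone at SV breakpoints and attach allele nodes.

    Deletions add a direct source→sink edge; insertions/VNTRs add a rank-1
    allele segment.  Walks take the alternate path exactly at carried SVs.
    """
    graph = PangenomeGraph()
    walks: dict[str, list[WalkRecord]] = {leaf: [] for leaf in leaves}
    by_chrom: dict[str, list[SVRecord]] = {c: [] for c in chrom_sizes}
    for sv in svs:
        by_chrom[sv.chrom].append(sv)
    alt_count = 0
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        cuts = {0, size}
        for sv in by_chrom[chrom]:
            cuts.add(sv.start)
            cuts.add(sv.end)
        bounds = sorted(cuts)
        tile_id: dict[int, str] = {}
        prev_id = None
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            sid = f"{chrom}s{i:05d}"
            graph.add_segment(sid, Segment(
                length=b - a, origin_sample=chrom, origin_offset=a,
                origin_rank=0))
            tile_id[a] = sid
            if prev_id is not None:
                graph.add_link(prev_id, "+", sid, "+")
            prev_id = sid
        for sv in sorted(by_chrom[chrom], key=lambda s: s.start):
            src = tile_id[bounds[bisect.bisect_left(bounds, sv.start) - 1]]
            fp = tile_id[sv.start]
            snk = tile_id[sv.end]
            if sv.alt_len == 0:  # deletion: direct edge
                graph.add_link(src, "+", snk, "+")
                alt_path = ((src, "+"), (snk, "+"))
            else:
                alt_count += 1
                aid = f"{chrom}a{alt_count:05d}"
                graph.add_segment(aid, Segment(
                    length=sv.alt_len,
                    origin_sample=min(sv.carriers) if sv.carriers else "alt",
                    origin_offset=0, origin_rank=1))
                graph.add_link(src, "+", aid, "+")
                graph.add_link(aid, "+", snk, "+")
                alt_path = ((src, "+"), (aid, "+"), (snk, "+"))
            ref_path = ((src, "+"), (fp, "+"), (snk, "+"))
            for leaf in leaves:
                path = alt_path if leaf in sv.carriers else ref_path
                walks[leaf].append(WalkRecord(
                    assembly=leaf, chrom=chrom,
                    ref_start=sv.start, ref_end=sv.end, path=path))
    graph.validate()
    return graph, walks


# ---------------------------------------------------------------------------
# annotation, depth and QC tracks


def _place_genes(config: SimConfig, svs: list[SVRecord],
                 rng: np.random.Generator) -> FeatureTrack:
    span = (config.cds_per_gene * config.cds_length
            + (config.cds_per_gene - 1) * config.intron_length)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chroms}
    for sv in svs:
        occupied[sv.chrom].append((sv.start, sv.end))
    feats = []
    for g in range(config.n_genes):
        name = f"g{g:04d}"
        for _try in range(200):
            chrom = config.chroms[int(rng.integers(0, config.n_chroms))]
            start = int(rng.integers(0, config.chrom_length - span))
            if config.gene_placement == "independent":
                break
            if not any(s < start + span and e > start
                       for s, e in occupied[chrom]):
                break
        else:
            # overcrowded: fall back to wherever the last draw landed
            pass
        feats.append(Feature(chrom, start, start + span, name, "gene"))
        pos = start
        for _x in range(config.cds_per_gene):
            feats.append(Feature(chrom, pos, pos + config.cds_length, name, "CDS"))
            pos += config.cds_length + config.intron_length
    return FeatureTrack(feats)


def _repeat_and_gap_tracks(config: SimConfig, rng: np.random.Generator
                           ) -> tuple[dict, dict]:
    repeats: dict[str, FeatureTrack] = {}
    gaps: dict[str, FeatureTrack] = {}
    for leaf in config.leaves:
        feats = []
        gap_feats = []
        for chrom in config.chroms:
            # proximal satellite: complete with probability p_satellite
            if rng.random() < config.p_satellite:
                sat = int(rng.integers(50_000, min(3_000_000, config.chrom_length // 2)))
            else:
                sat = int(rng.integers(0, 50_000))
            if sat > 0:
                feats.append(Feature(chrom, 0, sat, f"{chrom}_sat", "satellite"))
            # distal telomere: complete with probability p_telomere
            if rng.random() < config.p_telomere:
                tel = int(rng.integers(500, 3_001))
            else:
                tel = int(rng.integers(0, 500))
            if tel > 0:
                feats.append(Feature(
                    chrom, config.chrom_length - tel, config.chrom_length,
                    f"{chrom}_tel", "telomere"))
            for k in range(int(rng.poisson(1.5))):
                gs = int(rng.integers(0, config.chrom_length - 100))
                gap_feats.append(Feature(chrom, gs, gs + 100,
                                         f"{chrom}_gap{k}", "gap"))
        repeats[leaf] = FeatureTrack(feats)
        gaps[leaf] = FeatureTrack(gap_feats)
    return repeats, gaps


DROPOUT_BASE_P = 0.012
DROPOUT_DECAY = 0.1  # per fold-coverage


def _depth_tracks(config: SimConfig, cnvs: list[PlantedCNV],
                  rng: np.random.Generator) -> dict[str, DepthTrack]:
    tracks: dict[str, DepthTrack] = {}
    p_drop = DROPOUT_BASE_P * math.exp(-DROPOUT_DECAY * config.depth_mean)
    for leaf in config.leaves:
        wins = []
        for chrom in config.chroms:
            n_win = config.chrom_length // config.depth_window
            noise = rng.normal(1.0, config.depth_noise_cv, size=n_win)
            drop = rng.random(n_win) < p_drop
            drop_depth = rng.uniform(0.0, 0.8, size=n_win)
            for w in range(n_win):
                start = w * config.depth_window
                scale = 1.0
                for cnv in cnvs:
                    if (leaf in cnv.carriers and cnv.chrom == chrom
                            and start >= cnv.start
                            and start + config.depth_window <= cnv.end):
                        scale = 1.0 + cnv.extra_copies
                if drop[w]:
                    d = drop_depth[w]
                else:
                    d = max(0.0, config.depth_mean * scale * noise[w])
                wins.append(DepthWindow(chrom, start, config.depth_window, d))
        tracks[leaf] = DepthTrack(wins)
    return tracks


def _plant_cnvs(config: SimConfig,
                branches: list[tuple[str, float, frozenset]],
                rng: np.random.Generator) -> list[PlantedCNV]:
    cnvs = []
    internal = [b for b in branches if len(b[2]) >= 1]
    for _k in range(config.n_cnvs):
        chrom = config.chroms[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - config.cnv_length))
        start = (start // config.depth_window) * config.depth_window
        _bid, _len, clade = internal[int(rng.integers(0, len(internal)))]
        cnvs.append(PlantedCNV(chrom, start, start + config.cnv_length,
                               config.cnv_extra_copies, clade))
    return cnvs


def _contig_tables(config: SimConfig, rng: np.random.Generator
                   ) -> tuple[dict, dict, dict]:
    contigs: dict[str, list[int]] = {}
    blocks: dict[str, list[int]] = {}
    stats: dict[str, dict] = {}
    for leaf in config.leaves:
        lens: list[int] = []
        blens: list[int] = []
        for chrom in config.chroms:
            n_breaks = int(rng.poisson(1.5))
            cuts = sorted(rng.integers(1, config.chrom_length,
                                       size=n_breaks).tolist())
            bounds = [0] + cuts + [config.chrom_length]
            for a, b in zip(bounds, bounds[1:]):
                if b > a:
                    lens.append(b - a)
                    # phase blocks refine contigs
                    nb = 1 + int(rng.poisson(1.0))
                    if nb == 1 or b - a < 2 * nb:
                        blens.append(b - a)
                    else:
                        inner = sorted(rng.integers(a + 1, b, size=nb - 1).tolist())
                        bb = [a] + inner + [b]
                        blens.extend(y - x for x, y in zip(bb, bb[1:]) if y > x)
        total = sum(lens)
        true_qv = float(rng.uniform(40, 50))
        err = int(round(total * 10 ** (-true_qv / 10)))
        contigs[leaf] = lens
        blocks[leaf] = blens
        stats[leaf] = {"total_bases": total, "error_bases": err}
    return contigs, blocks, stats


# ---------------------------------------------------------------------------
# top level


def simulate_pangenome(config: SimConfig,
                       outdir: Optional[str] = None) -> SyntheticTruth:
    """Generate a full planted-truth pangenome; optionally emit all files.

    Deterministic given ``config.seed``: the same config and seed produce
    byte-identical output files.
    """
    rng = np.random.default_rng(config.seed)
    branches = tree_branches(config.tree_newick, config.leaves,
                             config.root_edge_length)
    svs, origins, details = draw_catalogue(config, rng)
    chrom_sizes = {c: config.chrom_length for c in config.chroms}
    graph, walks = build_graph_and_walks(svs, chrom_sizes, config.leaves)
    gene_track = _place_genes(config, svs, rng)
    repeats, gaps = _repeat_and_gap_tracks(config, rng)
    cnvs = _plant_cnvs(config, branches, rng)
    depth = _depth_tracks(config, cnvs, rng)
    contigs, blocks, stats = _contig_tables(config, rng)
    truth = SyntheticTruth(
        config=config, tree_newick=config.tree_newick, branches=branches,
        sv_catalogue=svs, sv_branch=origins, sv_alt_detail=details,
        chrom_sizes=chrom_sizes, graph=graph, walks=walks,
        gene_track=gene_track, repeat_tracks=repeats, gap_tracks=gaps,
        depth_tracks=depth, cnvs=cnvs, contigs=contigs, phase_blocks=blocks,
        assembly_stats=stats)
    if outdir is not None:
        truth.emit(outdir)
    return truth


# ---------------------------------------------------------------------------
# replicate perturbation


@dataclass
class Replicate:
    index: int
    sv_catalogue: list[SVRecord]
    graph: PangenomeGraph
    walks: dict[str, list[WalkRecord]]
    n_perturbed: int


def _split_sv(sv: SVRecord, neighbors_ok) -> Optional[list[SVRecord]]:
    """Split one event into two smaller ones at the same locus, or None."""
    if sv.alt_len == 0:  # deletion: halve the footprint with a 2 bp gap
        L = sv.ref_len
        if L < 102:
            return None
        L1 = (L - 2) // 2
        L2 = L - 2 - L1
        if L1 < 50 or L2 < 50:
            return None
        a = sv.start
        return [
            SVRecord(sv.chrom, a, a + L1, L1, 0, "DEL", sv.carriers),
            SVRecord(sv.chrom, a + L1 + 2, a + L1 + 2 + L2, L2, 0, "DEL",
                     sv.carriers),
        ]
    # insertion-like: two anchors 2 bp apart, alt length halved
    if sv.alt_len < 100:
        return None
    if not neighbors_ok(sv.chrom, sv.start - 2, sv.start + 6):
        return None
    A1 = sv.alt_len // 2
    A2 = sv.alt_len - A1
    a = sv.start
    return [
        SVRecord(sv.chrom, a, a + 1, 1, A1, sv_type(1, A1), sv.carriers),
        SVRecord(sv.chrom, a + 3, a + 4, 1, A2, sv_type(1, A2), sv.carriers),
    ]


def emit_replicates(truth: SyntheticTruth, n_replicates: int, noise: float,
                    seed: int, outdir: Optional[str] = None) -> list[Replicate]:
    """Stochastic pangenome re-constructions.

    Each replicate independently perturbs every bubble with probability
    ``noise``: perturbed events are dropped or split into two smaller
    events (half each; events too small to split are dropped).  This
    abstracts minigraph's sensitivity to assembly-integration order.
    """
    if not (0 <= noise < 1):
        raise ValueError("noise must be in [0, 1)")
    reps: list[Replicate] = []
    ivs_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sv in truth.sv_catalogue:
        ivs_by_chrom.setdefault(sv.chrom, []).append((sv.start, sv.end))
    for c in ivs_by_chrom:
        ivs_by_chrom[c].sort()

    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r, 7919])
        svs: list[SVRecord] = []
        n_pert = 0
        for sv in truth.sv_catalogue:
            if rng.random() >= noise:
                svs.append(sv)
                continue
            n_pert += 1
            if rng.random() < 0.5:
                continue  # dropped
            # splitting an insertion needs 2 bp of clear backbone beyond
            # the original 1 bp anchor on each side
            pieces = _split_sv(
                sv, lambda c, lo, hi, _own=(sv.start, sv.end): not any(
                    s < hi and e > lo and (s, e) != _own
                    for s, e in ivs_by_chrom.get(c, [])))
            if pieces is None:
                continue  # too small to split: dropped
            svs.extend(pieces)
        svs.sort(key=lambda s: (s.chrom, s.start))
        graph, walks = build_graph_and_walks(svs, truth.chrom_sizes,
                                             truth.config.leaves)
        rep = Replicate(r, svs, graph, walks, n_pert)
        reps.append(rep)
        if outdir is not None:
            rdir = Path(outdir) / f"rep{r:02d}"
            rdir.mkdir(parents=True, exist_ok=True)
            write_rgfa(graph, rdir / "graph.gfa")
            wdir = rdir / "walks"
            wdir.mkdir(exist_ok=True)
            for leaf, recs in walks.items():
                write_walks(recs, wdir / f"{leaf}.bed")
    return reps
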