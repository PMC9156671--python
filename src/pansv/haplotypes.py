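"""Retrace haplotype walks through bubbles into a bubble × assembly allele matrix.

Each matrix entry is the index of the path one assembly took through one
bubble, among the distinct observed paths at that site.  The reference path
is always allele 0.  Path identity is exact oriented segment-sequence
equality.  Assemblies with no record, a "." record, or multiple records at
one site (ambiguous) are MISSING there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bubbles import Bubble
from .graph_io import WalkRecord

log = logging.getLogger(__name__)

#: matrix encoding of a missing entry
MISSING_IDX = -1


@dataclass
class AlleleMatrix:
    bubble_keys: list[tuple[str, int, int]]
    assemblies: list[str]
    entries: np.ndarray  # int matrix, shape (n_bubbles, n_assemblies); -1 = MISSING
    allele_paths: dict[tuple[str, int, int], list[tuple]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=int)
        if self.entries.shape != (len(self.bubble_keys), len(self.assemblies)):
            raise ValueError("entry matrix shape disagrees with labels")

    @property
    def n_sites(self) -> int:
        return len(self.bubble_keys)

    def is_missing(self) -> np.ndarray:
        return self.entries == MISSING_IDX

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=self.assemblies)
        df.insert(0, "chrom", [k[0] for k in self.bubble_keys])
        df.insert(1, "start", [k[1] for k in self.bubble_keys])
        df.insert(2, "end", [k[2] for k in self.bubble_keys])
        return df

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        for a in self.assemblies:
            df[a] = df[a].map(lambda v: "." if v == MISSING_IDX else str(v))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AlleleMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        assemblies = [c for c in df.columns if c not in ("chrom", "start", "end")]
        ent = df[assemblies].replace(".", MISSING_IDX).astype(int).to_numpy()
        keys = list(zip(df.chrom, df.start.astype(int), df.end.astype(int)))
        return cls(keys, assemblies, ent)


def build_allele_matrix(
    bubbles: Sequence[Bubble],
    walks: Mapping[str, Sequence[WalkRecord]],
) -> AlleleMatrix:
    """Assign allele indices by matching walk records to bubble sites.

    Walk records are keyed by (chrom, ref_start, ref_end); records matching
    no bubble are ignored (counted in a warning).  A walk whose path
    endpoints are not the bubble's source/sink raises ValueError.
    """
    site_index = {b.site_key: i for i, b in enumerate(bubbles)}
    assemblies = list(walks.keys())
    # allele path registry per bubble, reference first when known
    paths: dict[tuple[str, int, int], list[tuple]] = {}
    for b in bubbles:
        paths[b.site_key] = [b.alleles[0]] if b.has_ref else []

    ent = np.full((len(bubbles), len(assemblies)), MISSING_IDX, dtype=int)
    n_unmatched = 0
    for j, asm in enumerate(assemblies):
        per_site: dict[tuple[str, int, int], list[WalkRecord]] = {}
        for rec in walks[asm]:
            key = rec.site_key
            if key not in site_index:
                n_unmatched += 1
                continue
            per_site.setdefault(key, []).append(rec)
        for key, recs in per_site.items():
            i = site_index[key]
            if len(recs) > 1:
                log.warning("ambiguous walk for %s at %s: %d records; "
                            "treated as MISSING", asm, key, len(recs))
                continue
            rec = recs[0]
            if rec.path is None:
                continue
            bub = bubbles[i]
            if rec.path[0][0] != bub.source_id or rec.path[-1][0] != bub.sink_id:
                raise ValueError(
                    f"walk endpoints {rec.path[0][0]}..{rec.path[-1][0]} do not "
                    f"match bubble {bub.source_id}..{bub.sink_id} at {key} "
                    f"for assembly {asm}")
            registry = paths[key]
            try:
                idx = registry.index(rec.path)
            except ValueError:
                registry.append(rec.path)
                idx = len(registry) - 1
            ent[i, j] = idx
    if n_unmatched:
        log.warning("%d walk record(s) matched no bubble site", n_unmatched)
    return AlleleMatrix([b.site_key for b in bubbles], assemblies, ent, paths)


def filter_complete(matrix: AlleleMatrix) -> tuple[AlleleMatrix, int]:
    """Drop every site with at least one MISSING entry; report the count."""
    keep = ~matrix.is_missing().any(axis=1)
    kept_keys = [k for k, f in zip(matrix.bubble_keys, keep) if f]
    out = AlleleMatrix(
        kept_keys,
        list(matrix.assemblies),
        matrix.entries[keep],
        {k: matrix.allele_paths[k] for k in kept_keys if k in matrix.allele_paths},
    )
    return out, int((~keep).sum())
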