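"""Greedy overlap-layout-consensus assembly of per-cluster contigs.

Read placements are derived from the verified similarity hits (strand and
diagonal offset), so no re-alignment is needed; the consensus is the column
majority over the layout.  This is deliberately simple: contigs only need to
be good enough for annotation and LTR harvesting, not finished assembly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cluster import SimilarityHit
from .io_utils import revcomp
from .simulate import _encode, _decode


@dataclass
class Contig:
    sequence: str
    n_reads: int

    def __len__(self) -> int:
        return len(self.sequence)


def _place_neighbor(hit: SimilarityHit, known: int, pos: int, orient: int,
                    len_a: int, len_b: int) -> tuple[int, int, int]:
    """Layout (node, pos, orient) of the other read of `hit` given `known`."""
    sign = 1 if hit.strand == "same" else -1
    d = hit.offset  # read_a coord u aligns to (b-frame) coord u - d
    if known == hit.read_b:
        o_a = orient * sign
        p_a = pos - d if o_a == 1 else pos + len_b - len_a + d
        return hit.read_a, p_a, o_a
    o_b = orient * sign
    p_b = pos + d if orient == 1 else pos + len_a - len_b - d
    return hit.read_b, p_b, o_b


def build_contigs(reads: Sequence[str], members: Sequence[int],
                  hits: Sequence[SimilarityHit],
                  cap_reads: int = 2000) -> list[Contig]:
    """Assemble contigs for one cluster.

    `members` are read indices of the cluster; `hits` may be the full hit
    table (it is filtered to the members used).  At most cap_reads members
    (largest hit-degree first) are laid out.
    """
    members = list(members)
    if not members:
        return []
    degree: dict[int, int] = defaultdict(int)
    member_set = set(members)
    adj: dict[int, list[SimilarityHit]] = defaultdict(list)
    for h in hits:
        if h.read_a in member_set and h.read_b in member_set:
            degree[h.read_a] += 1
            degree[h.read_b] += 1
            adj[h.read_a].append(h)
            adj[h.read_b].append(h)
    if len(members) > cap_reads:
        members = sorted(members, key=lambda m: (-degree[m], m))[:cap_reads]
        member_set = set(members)
    placed: dict[int, tuple[int, int]] = {}  # read -> (pos, orient)
    contigs: list[Contig] = []
    remaining = sorted(member_set, key=lambda m: (-degree[m], m))
    for seed in remaining:
        if seed in placed:
            continue
        # BFS layout of the component reachable from seed
        layout = {seed: (0, 1)}
        queue = [seed]
        while queue:
            cur = queue.pop(0)
            pos, orient = layout[cur]
            for h in sorted(adj[cur], key=lambda h: (h.read_a, h.read_b)):
                other = h.read_a if h.read_b == cur else h.read_b
                if other in layout or other not in member_set:
                    continue
                node, p, o = _place_neighbor(
                    h, cur, pos, orient, len(reads[h.read_a]), len(reads[h.read_b]))
                layout[node] = (p, o)
                queue.append(node)
        placed.update(layout)
        contigs.append(_consensus(reads, layout))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def _consensus(reads: Sequence[str], layout: dict[int, tuple[int, int]]) -> Contig:
    lo = min(p for p, _ in layout.values())
    hi = max(p + len(reads[r]) for r, (p, _) in layout.items())
    counts = np.zeros((4, hi - lo), dtype=np.int32)
    for r, (p, o) in layout.items():
        seq = reads[r] if o == 1 else revcomp(reads[r])
        arr = _encode(seq)
        counts[arr, np.arange(p - lo, p - lo + arr.size)] += 1
    covered = counts.sum(axis=0) > 0
    cons = counts.argmax(axis=0).astype(np.uint8)  # ties -> smallest base
    return Contig(_decode(cons[covered]), n_reads=len(layout))
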