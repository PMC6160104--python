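"""Cross-population CNVR comparison: shared/unique counts and Venn partition.

The counting unit is focal-set regions: a region of population A counts as
"shared with B" when at least one region of B overlaps it by >= 1 bp.  This
makes sharedness directional — |A shared with B| need not equal |B shared
with A| — so both directions are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from cnvpop.cnvr import CnvRegion


@dataclass
class OverlapReport:
    populations: list[str]
    totals: dict[str, int]
    #: per focal population: {frozenset of other populations overlapped: count}
    venn_counts: dict[str, dict[frozenset[str], int]]
    unique_counts: dict[str, int]
    all_shared_counts: dict[str, int]
    #: (focal, other) -> number of focal regions overlapped by >= 1 other region
    pairwise_shared: dict[tuple[str, str], int]
    #: (focal, other) -> fraction of focal regions shared
    pairwise_fraction: dict[tuple[str, str], float]
    #: (focal, other) -> total bp of focal regions labeled shared
    shared_length_bp: dict[tuple[str, str], int]


def _overlaps_any(region: CnvRegion, others: Sequence[CnvRegion]) -> bool:
    return any(region.overlaps(o.chrom, o.start, o.end) for o in others)


def _index_by_chrom(regions: Sequence[CnvRegion]) -> dict[str, list[CnvRegion]]:
    idx: dict[str, list[CnvRegion]] = {}
    for r in regions:
        idx.setdefault(r.chrom, []).append(r)
    for chunk in idx.values():
        chunk.sort(key=lambda r: (r.start, r.end))
    return idx


def _shared_mask(focal: Sequence[CnvRegion], other: Sequence[CnvRegion]) -> list[bool]:
    """For each focal region, whether >= 1 bp of some other-set region overlaps it."""
    other_idx = _index_by_chrom(other)
    mask = []
    for r in focal:
        candidates = other_idx.get(r.chrom, ())
        # sorted scan; regions lists are small enough that no interval tree is needed
        mask.append(any(o.start <= r.end and r.start <= o.end for o in candidates))
    return mask


def overlap_regions(
    set_a: Sequence[CnvRegion], set_b: Sequence[CnvRegion]
) -> tuple[list[CnvRegion], list[CnvRegion], list[tuple[CnvRegion, CnvRegion]]]:
    """Split A into (shared-with-B, unique) and list all overlapping pairs."""
    mask = _shared_mask(set_a, set_b)
    a_shared = [r for r, m in zip(set_a, mask) if m]
    a_unique = [r for r, m in zip(set_a, mask) if not m]
    b_idx = _index_by_chrom(set_b)
    pairs = [
        (a, b)
        for a in a_shared
        for b in b_idx.get(a.chrom, ())
        if b.start <= a.end and a.start <= b.end
    ]
    return a_shared, a_unique, pairs


def venn_partition(sets: Mapping[str, Sequence[CnvRegion]]) -> OverlapReport:
    """Label every region of every population by the other populations it overlaps.

    Supports two or three populations.  For each focal population the Venn
    cell counts sum to its total region count; "all shared" means the region
    overlaps every other population's set.
    """
    pops = list(sets)
    if not 2 <= len(pops) <= 3:
        raise ValueError(f"venn_partition supports 2-3 populations, got {len(pops)}")

    venn_counts: dict[str, dict[frozenset[str], int]] = {}
    unique_counts: dict[str, int] = {}
    all_shared: dict[str, int] = {}
    pairwise_shared: dict[tuple[str, str], int] = {}
    pairwise_fraction: dict[tuple[str, str], float] = {}
    shared_length: dict[tuple[str, str], int] = {}

    for focal in pops:
        others = [p for p in pops if p != focal]
        masks = {p: _shared_mask(sets[focal], sets[p]) for p in others}
        cells: dict[frozenset[str], int] = {}
        for i, region in enumerate(sets[focal]):
            label = frozenset(p for p in others if masks[p][i])
            cells[label] = cells.get(label, 0) + 1
        venn_counts[focal] = cells
        unique_counts[focal] = cells.get(frozenset(), 0)
        all_shared[focal] = cells.get(frozenset(others), 0)
        for p in others:
            n_shared = sum(masks[p])
            pairwise_shared[(focal, p)] = n_shared
            total = len(sets[focal])
            pairwise_fraction[(focal, p)] = n_shared / total if total else 0.0
            shared_length[(focal, p)] = sum(
                r.length_bp for r, m in zip(sets[focal], masks[p]) if m
            )

    return OverlapReport(
        populations=pops,
        totals={p: len(sets[p]) for p in pops},
        venn_counts=venn_counts,
        unique_counts=unique_counts,
        all_shared_counts=all_shared,
        pairwise_shared=pairwise_shared,
        pairwise_fraction=pairwise_fraction,
        shared_length_bp=shared_length,
    )
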