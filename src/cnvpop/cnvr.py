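"""Merge per-sample CNV calls into CNV regions (CNVRs) and summarize them.

A CNVR is the union extent of all calls connected by >= 1 bp of mutual
overlap on 1-based inclusive coordinates — mergeBed semantics, except that
book-ended inclusive intervals sharing exactly one base pair DO merge, since
they genuinely overlap by one bp.  Region state is "gain" when every member
call is a duplication (TCN > 2), "loss" when every member is a deletion
(TCN < 2), and "complex" otherwise.

Region length is defined as ``end - start``; published CNVR tables in this
field satisfy length = end - start exactly, so that convention is kept even
though it differs from the inclusive bp count by one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cnvpop.io import CnvCall, _chrom_sort_key

LENGTH_CLASSES = ("1-10kb", "10-100kb", ">100kb")
FREQUENCY_CLASSES = ("singleton", "rare", "moderate", "recurring")


@dataclass(frozen=True)
class CnvRegion:
    """A merged CNV region with its state and carrier set."""

    chrom: str
    start: int
    end: int
    state: str  # gain | loss | complex
    carriers: frozenset[str]
    member_calls: tuple[CnvCall, ...] = ()

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """>= 1 bp overlap on 1-based inclusive coordinates."""
        return self.chrom == chrom and self.start <= end and start <= self.end


def classify_state(tcns: Iterable[int]) -> str:
    """gain if all TCN > 2, loss if all < 2, complex for a mixture."""
    tcns = list(tcns)
    if not tcns:
        raise ValueError("cannot classify a region with no member calls")
    if all(t > 2 for t in tcns):
        return "gain"
    if all(t < 2 for t in tcns):
        return "loss"
    return "complex"


def merge_calls_to_regions(calls: Sequence[CnvCall]) -> list[CnvRegion]:
    """Merge calls into CNVRs: connected components of >= 1 bp overlap.

    Calls are processed per chromosome with a sorted sweep; because overlap
    of 1-based inclusive intervals [a,b], [c,d] means a <= d and c <= b, a
    sorted call starts a new region exactly when its start exceeds the
    current region's running end.  Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for call in calls:
        by_chrom.setdefault(call.chrom, []).append(call)

    regions: list[CnvRegion] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.sample_id))
        cluster: list[CnvCall] = []
        cur_end = -1
        for call in chunk:
            if cluster and call.start > cur_end:
                regions.append(_finalize(chrom, cluster))
                cluster = []
                cur_end = -1
            cluster.append(call)
            cur_end = max(cur_end, call.end)
        if cluster:
            regions.append(_finalize(chrom, cluster))
    return regions


def _finalize(chrom: str, members: list[CnvCall]) -> CnvRegion:
    return CnvRegion(
        chrom=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        state=classify_state(c.tcn for c in members),
        carriers=frozenset(c.sample_id for c in members),
        member_calls=tuple(members),
    )


def assign_length_class(length_bp: int) -> tuple[str, bool]:
    """Length class with half-open boundaries [1kb,10kb), [10kb,100kb), [100kb,inf).

    Returns ``(label, flagged)``; lengths below 1 kb fall in the first class
    and come back flagged rather than silently dropped.
    """
    if length_bp < 1_000:
        return LENGTH_CLASSES[0], True
    if length_bp < 10_000:
        return LENGTH_CLASSES[0], False
    if length_bp < 100_000:
        return LENGTH_CLASSES[1], False
    return LENGTH_CLASSES[2], False


def assign_frequency_class(n_carriers: int) -> str:
    """singleton = 1 carrier, rare = 2-4, moderate = 5-15, recurring >= 16.

    Carriers are distinct individuals: a sample contributing several adjacent
    calls to one region still counts once.
    """
    if n_carriers < 1:
        raise ValueError("a region must have at least one carrier")
    if n_carriers == 1:
        return "singleton"
    if n_carriers <= 4:
        return "rare"
    if n_carriers <= 15:
        return "moderate"
    return "recurring"


def summarize_regions(
    regions: Sequence[CnvRegion], chrom_sizes: Mapping[str, int]
) -> dict[str, pd.DataFrame]:
    """Descriptive statistics: per-state, per-chromosome and class tables.

    Coverage is total region bp divided by total autosome bp; missing
    chromosome sizes raise immediately.
    """
    for r in regions:
        if r.chrom not in chrom_sizes:
            raise KeyError(f"no chromosome size for {r.chrom!r}")
    genome = sum(chrom_sizes.values())

    rows = []
    for r in regions:
        lclass, flagged = assign_length_class(r.length_bp)
        rows.append(
            {
                "region_id": r.region_id, "chrom": r.chrom, "start": r.start,
                "end": r.end, "length_bp": r.length_bp, "state": r.state,
                "n_carriers": r.n_carriers,
                "length_class": lclass, "sub_kb_flag": flagged,
                "frequency_class": assign_frequency_class(r.n_carriers),
            }
        )
    table = pd.DataFrame(rows)

    def _stats(sub: pd.DataFrame) -> dict:
        return {
            "n": len(sub),
            "mean_length": sub["length_bp"].mean() if len(sub) else float("nan"),
            "min_length": sub["length_bp"].min() if len(sub) else float("nan"),
            "max_length": sub["length_bp"].max() if len(sub) else float("nan"),
            "coverage_frac": sub["length_bp"].sum() / genome,
        }

    by_state = pd.DataFrame(
        {state: _stats(table[table["state"] == state]) for state in ("gain", "loss", "complex")}
        | {"all": _stats(table)}
    ).T
    by_state["n"] = by_state["n"].astype(int)

    by_chrom = (
        table.groupby("chrom", sort=False)
        .agg(n=("region_id", "size"), total_bp=("length_bp", "sum"))
        .reset_index()
    )
    by_chrom["coverage_frac"] = by_chrom.apply(
        lambda row: row["total_bp"] / chrom_sizes[row["chrom"]], axis=1
    )

    length_counts = (
        table["length_class"].value_counts().reindex(LENGTH_CLASSES, fill_value=0).rename("n")
    )
    freq_counts = (
        table["frequency_class"].value_counts().reindex(FREQUENCY_CLASSES, fill_value=0).rename("n")
    )
    return {
        "regions": table,
        "by_state": by_state,
        "by_chrom": by_chrom,
        "length_class_counts": length_counts.to_frame(),
        "frequency_class_counts": freq_counts.to_frame(),
    }
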