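"""Interval-join CNVRs against gene and QTL tracks and summarize gene content.

A feature annotates a region when the two intervals share at least one base
pair on 1-based inclusive coordinates; there is no nearest-gene fallback.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from cnvpop.cnvr import CnvRegion
from cnvpop.io import AnnotationFeature


def annotate_regions(
    regions: Sequence[CnvRegion], track: Sequence[AnnotationFeature]
) -> dict[str, list[AnnotationFeature]]:
    """Map region_id -> ordered feature list (>= 1 bp overlap required).

    Features come back sorted by (start, end, feature_id) within each region.
    """
    by_chrom: dict[str, list[AnnotationFeature]] = {}
    for f in track:
        by_chrom.setdefault(f.chrom, []).append(f)
    for feats in by_chrom.values():
        feats.sort(key=lambda f: (f.start, f.end, f.feature_id))

    out: dict[str, list[AnnotationFeature]] = {}
    for r in regions:
        out[r.region_id] = [
            f for f in by_chrom.get(r.chrom, ())
            if f.start <= r.end and r.start <= f.end
        ]
    return out


def gene_content_summary(
    annotated: dict[str, list[AnnotationFeature]]
) -> tuple[int, float, int, float]:
    """(n regions with >= 1 gene, fraction, n without, fraction).

    QTL features do not count toward gene content.
    """
    total = len(annotated)
    if total == 0:
        raise ValueError("no regions to summarize")
    n_with = sum(
        1 for feats in annotated.values() if any(f.feature_class == "gene" for f in feats)
    )
    n_without = total - n_with
    return n_with, n_with / total, n_without, n_without / total


def annotation_to_frame(
    regions: Sequence[CnvRegion], annotated: dict[str, list[AnnotationFeature]]
) -> pd.DataFrame:
    rows = []
    for r in regions:
        feats = annotated.get(r.region_id, [])
        genes = [f for f in feats if f.feature_class == "gene"]
        qtls = [f for f in feats if f.feature_class == "qtl"]
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "state": r.state,
                "n_carriers": r.n_carriers,
                "genes": ";".join(f.feature_name or f.feature_id for f in genes),
                "qtl": ";".join(f.feature_id for f in qtls),
            }
        )
    return pd.DataFrame(rows)
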