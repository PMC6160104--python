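"""Individual x CNVR matrices for population-genetic analyses.

Two encodings mirror the two standard ways of scoring CNV genotypes:

* ``presence`` — 1 if the sample has >= 1 call overlapping the region, else 0;
* ``copy_number`` — the total copy number (0/1/3/4) of the sample's
  overlapping call, with 2 (neutral) where the sample has none.

When several of a sample's calls overlap one (typically complex) region, the
call covering the most bp of the region wins; ties go to the more extreme
state (larger |tcn - 2|), and a deletion beats a duplication on an exact tie.

``filter_min_carriers`` implements the recurrence filter used before
cross-population work: keep only regions carried by >= k individuals, either
overall or within every population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cnvpop.cnvr import CnvRegion
from cnvpop.io import CnvCall

ENCODINGS = ("presence", "copy_number")


@dataclass
class CnvMatrix:
    samples: list[str]
    regions: list[CnvRegion]
    values: np.ndarray  # samples x regions, integer codes
    encoding: str

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"encoding must be one of {ENCODINGS}")
        if self.values.shape != (len(self.samples), len(self.regions)):
            raise ValueError("values shape does not match samples x regions")
        codes = set(np.unique(self.values).tolist())
        allowed = {0, 1} if self.encoding == "presence" else {0, 1, 2, 3, 4}
        if not codes <= allowed:
            raise ValueError(f"codes {codes - allowed} invalid for {self.encoding}")

    def carrier_counts(self, manifest: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Carriers per region, overall or broken down by population."""
        carried = (
            self.values != 0 if self.encoding == "presence" else self.values != 2
        )
        region_ids = [r.region_id for r in self.regions]
        if manifest is None:
            return pd.DataFrame({"region_id": region_ids, "n_carriers": carried.sum(axis=0)})
        pops = pd.Series([manifest[s] for s in self.samples], name="population")
        df = pd.DataFrame(carried, columns=region_ids)
        out = df.groupby(pops).sum().T
        out.index.name = "region_id"
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.samples, columns=[r.region_id for r in self.regions]
        )


def _pick_call(calls: list[tuple[CnvCall, int]]) -> int:
    """Resolve multiple overlapping calls: most covered bp, then extremity,
    then deletion-first; returns the winning tcn."""
    def key(item: tuple[CnvCall, int]):
        call, covered = item
        return (-covered, -abs(call.tcn - 2), call.tcn)
    return min(calls, key=key)[0].tcn


def build_matrix(
    regions: Sequence[CnvRegion],
    calls: Sequence[CnvCall],
    manifest: Mapping[str, str],
    encoding: str = "presence",
) -> CnvMatrix:
    """Score every manifest sample against every region."""
    if encoding not in ENCODINGS:
        raise ValueError(f"encoding must be one of {ENCODINGS}")
    unknown = sorted({c.sample_id for c in calls} - set(manifest))
    if unknown:
        raise ValueError(f"sample(s) in calls absent from manifest: {unknown}")

    samples = list(manifest)
    sample_idx = {s: i for i, s in enumerate(samples)}
    region_idx: dict[str, list[tuple[int, CnvRegion]]] = {}
    for j, r in enumerate(regions):
        region_idx.setdefault(r.chrom, []).append((j, r))

    neutral = 0 if encoding == "presence" else 2
    values = np.full((len(samples), len(regions)), neutral, dtype=int)
    hits: dict[tuple[int, int], list[tuple[CnvCall, int]]] = {}
    for call in calls:
        i = sample_idx[call.sample_id]
        for j, r in region_idx.get(call.chrom, ()):
            if call.start <= r.end and r.start <= call.end:
                covered = min(call.end, r.end) - max(call.start, r.start) + 1
                hits.setdefault((i, j), []).append((call, covered))
    for (i, j), overlapping in hits.items():
        values[i, j] = 1 if encoding == "presence" else _pick_call(overlapping)
    return CnvMatrix(samples=samples, regions=list(regions), values=values, encoding=encoding)


def filter_min_carriers(
    matrix: CnvMatrix,
    k: int,
    per_population: bool = False,
    manifest: Mapping[str, str] | None = None,
) -> CnvMatrix:
    """Keep regions with >= k carriers (within every population if requested).

    Sample order is untouched; surviving regions keep their relative order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    carried = matrix.values != (0 if matrix.encoding == "presence" else 2)
    if per_population:
        if manifest is None:
            raise ValueError("per_population filtering requires a manifest")
        pops = np.asarray([manifest[s] for s in matrix.samples])
        keep = np.ones(len(matrix.regions), dtype=bool)
        for pop in np.unique(pops):
            keep &= carried[pops == pop].sum(axis=0) >= k
    else:
        keep = carried.sum(axis=0) >= k
    return CnvMatrix(
        samples=matrix.samples,
        regions=[r for r, m in zip(matrix.regions, keep) if m],
        values=matrix.values[:, keep],
        encoding=matrix.encoding,
    )


def write_matrix(matrix: CnvMatrix, path) -> None:
    matrix.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")
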