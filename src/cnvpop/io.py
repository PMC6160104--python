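"""Readers and writers for the tab-delimited tables the pipeline consumes.

Coordinate conventions
----------------------
All in-memory coordinates are 1-based inclusive, the dialect PennCNV call
tables use.  BED export converts to 0-based half-open ``(start - 1, end)``;
a sidecar TSV written next to each BED preserves the 1-based coordinates so
that read(write(x)) round-trips exactly.

Missing signal values are kept as NaN — they are excluded pairwise from any
downstream variance, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_TCN = frozenset({0, 1, 3, 4})


class ParseError(ValueError):
    """A malformed row in an input table; the message names the line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a schema invariant."""


@dataclass(frozen=True)
class SnpProbe:
    """One array probe: id, chromosome, 1-based position, GC fraction."""

    probe_id: str
    chrom: str
    pos: int
    gc_frac: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id}: pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.gc_frac <= 1.0:
            raise ValidationError(
                f"probe {self.probe_id}: gc_frac must be in [0, 1], got {self.gc_frac}"
            )


@dataclass(frozen=True)
class CnvCall:
    """A per-sample CNV event with total copy number (TCN) support.

    TCN 0/1 are deletions of two/one copies, 3/4 single/double duplications.
    TCN 2 is the neutral state and by definition never appears in a call.
    Coordinates are 1-based inclusive.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    tcn: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.tcn not in VALID_TCN:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"tcn must be one of {sorted(VALID_TCN)}, got {self.tcn}"
            )
        if self.n_snps < 1:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: n_snps < 1"
            )


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene or QTL interval on 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    feature_id: str
    feature_name: str
    feature_class: str  # "gene" or "qtl"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"feature {self.feature_id}: start > end")
        if self.feature_class not in ("gene", "qtl"):
            raise ValidationError(
                f"feature {self.feature_id}: feature_class must be 'gene' or 'qtl'"
            )


@dataclass
class SignalMatrix:
    """Probes x samples LRR values (NaN = missing), aligned to a probe map.

    ``lrr`` has one row per probe in ``probes`` (sorted by chrom, pos) and one
    column per entry of ``samples``.  ``baf`` is optional and shares the shape.
    """

    probes: list[SnpProbe]
    samples: list[str]
    lrr: np.ndarray
    baf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lrr.shape != (len(self.probes), len(self.samples)):
            raise ValidationError(
                f"LRR shape {self.lrr.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        if self.baf is not None and self.baf.shape != self.lrr.shape:
            raise ValidationError("BAF shape does not match LRR shape")

    def sample_lrr(self, sample_id: str) -> np.ndarray:
        return self.lrr[:, self.samples.index(sample_id)]

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([p.chrom for p in self.probes])

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([p.pos for p in self.probes], dtype=np.int64)

    @property
    def gc(self) -> np.ndarray:
        return np.asarray([p.gc_frac for p in self.probes], dtype=float)


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Numeric chromosome labels sort numerically, others lexically after."""
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def sort_probes(probes: Iterable[SnpProbe]) -> list[SnpProbe]:
    return sorted(probes, key=lambda p: (_chrom_sort_key(p.chrom), p.pos))


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_snp_map(path: str | Path) -> list[SnpProbe]:
    """Read a probe map TSV (probe_id, chrom, pos, gc_frac), sorted on return."""
    df = _read_tsv(path, ["probe_id", "chrom", "pos", "gc_frac"])
    probes = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            probe = SnpProbe(row.probe_id, row.chrom, int(row.pos), float(row.gc_frac))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        key = (probe.chrom, probe.pos)
        if key in seen:
            raise ValidationError(f"{path}: duplicate probe position {key}")
        seen.add(key)
        probes.append(probe)
    return sort_probes(probes)


def read_cnv_calls(path: str | Path, known_chroms: set[str] | None = None) -> list[CnvCall]:
    """Read a PennCNV-style call table; rows with tcn == 2 are rejected."""
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "tcn", "n_snps"])
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            call = CnvCall(
                row.sample_id, row.chrom, int(row.start), int(row.end), int(row.tcn), int(row.n_snps)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        if known_chroms is not None and call.chrom not in known_chroms:
            raise ValidationError(f"{path}: line {i}: unknown chromosome {call.chrom!r}")
        calls.append(call)
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    pd.DataFrame(
        [(c.sample_id, c.chrom, c.start, c.end, c.tcn, c.n_snps) for c in calls],
        columns=["sample_id", "chrom", "start", "end", "tcn", "n_snps"],
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read the sample -> population manifest; sample ids must be unique."""
    df = _read_tsv(path, ["sample_id", "population"])
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"{path}: duplicate sample id(s) {dupes}")
    return dict(zip(df["sample_id"], df["population"]))


def write_manifest(manifest: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(manifest.items(), columns=["sample_id", "population"]).to_csv(
        path, sep="\t", index=False
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = _read_tsv(path, ["chrom", "length_bp"])
    sizes = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        length = int(row.length_bp)
        if length <= 0:
            raise ValidationError(f"{path}: line {i}: length_bp must be > 0")
        if row.chrom in sizes:
            raise ValidationError(f"{path}: line {i}: duplicate chromosome {row.chrom!r}")
        sizes[row.chrom] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sizes.items(), columns=["chrom", "length_bp"]).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[AnnotationFeature]:
    df = _read_tsv(path, ["chrom", "start", "end", "feature_id", "feature_name", "feature_class"])
    features = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            features.append(
                AnnotationFeature(
                    row.chrom, int(row.start), int(row.end),
                    row.feature_id, row.feature_name, row.feature_class,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return features


def read_signal_matrix(
    path: str | Path, probes: Sequence[SnpProbe], baf_path: str | Path | None = None
) -> SignalMatrix:
    """Read a probes x samples LRR TSV aligned against a probe map.

    The file's first column is ``probe_id``; remaining columns are samples.
    Rows may appear in any order; the returned matrix follows the map order.
    "NA" and empty cells become NaN.
    """
    probes = sort_probes(probes)
    known = {p.probe_id for p in probes}

    def _load(p: str | Path) -> pd.DataFrame:
        df = pd.read_csv(p, sep="\t", index_col="probe_id", na_values=["NA"])
        unknown = sorted(set(df.index) - known)
        if unknown:
            raise ValidationError(f"{p}: probe id(s) not in map: {unknown}")
        absent = [pr.probe_id for pr in probes if pr.probe_id not in df.index]
        if absent:
            raise ValidationError(f"{p}: map probe(s) missing from file: {absent}")
        return df.loc[[pr.probe_id for pr in probes]]

    lrr_df = _load(path)
    baf = None
    if baf_path is not None:
        baf_df = _load(baf_path)
        if list(baf_df.columns) != list(lrr_df.columns):
            raise ValidationError("BAF and LRR files have different sample columns")
        baf = baf_df.to_numpy(dtype=float)
    return SignalMatrix(
        probes=list(probes),
        samples=list(lrr_df.columns),
        lrr=lrr_df.to_numpy(dtype=float),
        baf=baf,
    )


def write_signal_matrix(signal: SignalMatrix, path: str | Path, which: str = "lrr") -> None:
    values = signal.lrr if which == "lrr" else signal.baf
    if values is None:
        raise ValueError(f"signal matrix has no {which} layer")
    df = pd.DataFrame(values, columns=signal.samples)
    df.insert(0, "probe_id", [p.probe_id for p in signal.probes])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_snp_map(probes: Iterable[SnpProbe], path: str | Path) -> None:
    pd.DataFrame(
        [(p.probe_id, p.chrom, p.pos, p.gc_frac) for p in probes],
        columns=["probe_id", "chrom", "pos", "gc_frac"],
    ).to_csv(path, sep="\t", index=False)


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return bed_start + 1, bed_end


def write_regions_bed(regions: Sequence, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write CNVRs as BED plus a 1-based sidecar TSV with state and carriers.

    The BED carries converted 0-based half-open coordinates for interop with
    genome browsers; the sidecar (default: ``<path>.tsv``) is the lossless
    representation read back by :func:`read_regions_tsv`.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".tsv")
    with open(path, "w") as fh:
        fh.write("# CNVR export, BED 0-based half-open\n")
        for r in regions:
            b0, b1 = to_bed_interval(r.start, r.end)
            fh.write(f"{r.chrom}\t{b0}\t{b1}\t{r.region_id}\n")
    rows = [
        (r.region_id, r.chrom, r.start, r.end, r.length_bp, r.state,
         r.n_carriers, ";".join(sorted(r.carriers)))
        for r in regions
    ]
    pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "length_bp", "state",
                 "n_carriers", "carriers"],
    ).to_csv(sidecar, sep="\t", index=False)


def read_regions_tsv(path: str | Path):
    """Read a sidecar region TSV back into CnvRegion objects (no member calls)."""
    from cnvpop.cnvr import CnvRegion  # local import to avoid a cycle

    df = _read_tsv(path, ["chrom", "start", "end", "state", "carriers"])
    regions = []
    for row in df.itertuples(index=False):
        carriers = frozenset(row.carriers.split(";")) if row.carriers else frozenset()
        regions.append(
            CnvRegion(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                state=row.state, carriers=carriers, member_calls=(),
            )
        )
    return regions
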