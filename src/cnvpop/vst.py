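"""V_ST scan for population-differentiated CNV regions.

V_ST is an F_ST analog computed on continuous array intensities rather than
allele frequencies.  For one SNP probe and a pair of populations,

    V_ST = (V_T - V_S) / V_T

where V_T is the variance of LRR values pooled over both populations and
V_S = (n1*V1 + n2*V2) / (n1 + n2) is the within-population variance weighted
by population size.  Population (divide-by-n) variances are used throughout,
which makes V_ST exactly 0 when the two populations hold identical value
multisets and exactly 1 when each population is internally constant at a
different level.  Sampling noise can push the raw value slightly negative;
it is clamped to [0, 1] with the raw value retained.

Probe values inside a CNVR are averaged into the region's mean V_ST.  The
scan flags regions under two rules: ``mean2sd`` (mean + 2 SD of the scanned
mean V_ST distribution, strict >) and ``top5pct`` (the 95th percentile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cnvpop.cnvr import CnvRegion
from cnvpop.io import SignalMatrix

THRESHOLD_RULES = ("mean2sd", "top5pct")


class UndefinedVstError(ValueError):
    """V_ST has no value (too few usable observations)."""


@dataclass
class VstResult:
    region: CnvRegion
    pair: tuple[str, str]
    snp_vst: np.ndarray        # clamped per-probe values
    snp_vst_raw: np.ndarray    # before clamping
    mean_vst: float
    raw_mean_vst: float
    n_snps: int
    n_skipped: int
    significant: bool = False
    threshold_used: float = float("nan")
    rule: str = ""
    flags: dict[str, bool] = field(default_factory=dict)


def snp_vst(
    lrr_pop1: np.ndarray, lrr_pop2: np.ndarray, unbiased: bool = False
) -> tuple[float, float]:
    """Per-SNP V_ST for two populations; returns (clamped, raw).

    Missing values are dropped per population; each needs >= 2 observations.
    ``unbiased`` switches to n-1 variances (the size weighting then no longer
    cancels exactly for identical populations).
    """
    x1 = np.asarray(lrr_pop1, dtype=float)
    x2 = np.asarray(lrr_pop2, dtype=float)
    x1 = x1[~np.isnan(x1)]
    x2 = x2[~np.isnan(x2)]
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise UndefinedVstError(f"need >= 2 values per population, got {n1} and {n2}")
    ddof = 1 if unbiased else 0
    v_t = float(np.var(np.concatenate([x1, x2]), ddof=ddof))
    if v_t == 0.0:
        return 0.0, 0.0
    v_s = (n1 * float(np.var(x1, ddof=ddof)) + n2 * float(np.var(x2, ddof=ddof))) / (n1 + n2)
    raw = (v_t - v_s) / v_t
    return float(np.clip(raw, 0.0, 1.0)), raw


def region_vst(
    region: CnvRegion,
    signal: SignalMatrix,
    manifest: Mapping[str, str],
    pair: tuple[str, str],
    unbiased: bool = False,
) -> VstResult:
    """Mean V_ST over every probe positioned inside the region (closed interval).

    Probes where either population has fewer than two non-missing values are
    skipped and counted in ``n_skipped``.
    """
    pop1, pop2 = pair
    cols1 = [j for j, s in enumerate(signal.samples) if manifest.get(s) == pop1]
    cols2 = [j for j, s in enumerate(signal.samples) if manifest.get(s) == pop2]
    if not cols1 or not cols2:
        raise UndefinedVstError(f"pair {pair}: one population has no samples in the signal")

    in_region = np.flatnonzero(
        (signal.chroms == region.chrom)
        & (signal.positions >= region.start)
        & (signal.positions <= region.end)
    )
    values, raws = [], []
    skipped = 0
    for idx in in_region:
        try:
            v, raw = snp_vst(signal.lrr[idx, cols1], signal.lrr[idx, cols2], unbiased=unbiased)
        except UndefinedVstError:
            skipped += 1
            continue
        values.append(v)
        raws.append(raw)
    if not values:
        raise UndefinedVstError(f"region {region.region_id}: no usable probes")
    return VstResult(
        region=region,
        pair=pair,
        snp_vst=np.asarray(values),
        snp_vst_raw=np.asarray(raws),
        mean_vst=float(np.mean(values)),
        raw_mean_vst=float(np.mean(raws)),
        n_snps=len(values),
        n_skipped=skipped,
    )


def vst_scan(
    regions: Sequence[CnvRegion],
    signal: SignalMatrix,
    manifest: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    threshold_rule: str = "mean2sd",
    min_carriers: int = 5,
    carrier_counts=None,
    unbiased: bool = False,
) -> list[VstResult]:
    """Pairwise V_ST with the per-breed recurrence filter, flagging outliers.

    ``carrier_counts`` is a region_id x population table of carrier counts
    (as returned by :meth:`cnvpop.matrix.CnvMatrix.carrier_counts`); for each
    pair, only regions carried by >= ``min_carriers`` individuals in *both*
    populations of that pair enter the scan.  Without carrier counts every
    region is scanned.  Thresholds are computed per pair across its scanned
    regions; every result records its status under both rules in ``flags``
    and its ``significant`` flag under ``threshold_rule``.
    """
    if threshold_rule not in THRESHOLD_RULES:
        raise ValueError(f"threshold_rule must be one of {THRESHOLD_RULES}")
    out: list[VstResult] = []
    for pair in pairs:
        scanned = list(regions)
        if carrier_counts is not None:
            scanned = [
                r for r in scanned
                if all(
                    r.region_id in carrier_counts.index
                    and carrier_counts.loc[r.region_id, pop] >= min_carriers
                    for pop in pair
                )
            ]
        results = []
        for region in scanned:
            try:
                results.append(region_vst(region, signal, manifest, pair, unbiased=unbiased))
            except UndefinedVstError:
                continue
        if not results:
            continue
        means = np.asarray([r.mean_vst for r in results])
        if len(results) < 20:
            warnings.warn(
                f"pair {pair}: only {len(results)} scanned regions; "
                "the top-5% quantile threshold is unstable",
                stacklevel=2,
            )
        thresholds = {
            "mean2sd": float(means.mean() + 2.0 * means.std(ddof=1)) if len(means) > 1
            else float("inf"),
            "top5pct": float(np.quantile(means, 0.95)),
        }
        for r in results:
            r.flags = {
                "mean2sd": r.mean_vst > thresholds["mean2sd"],
                "top5pct": r.mean_vst > thresholds["top5pct"],
            }
            r.rule = threshold_rule
            r.threshold_used = thresholds[threshold_rule]
            r.significant = r.flags[threshold_rule]
        out.extend(results)
    return out


def scan_to_frame(results: Sequence[VstResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "region_id": [r.region.region_id for r in results],
            "chrom": [r.region.chrom for r in results],
            "start": [r.region.start for r in results],
            "end": [r.region.end for r in results],
            "pair": [f"{a}-{b}" for a, b in (r.pair for r in results)],
            "n_snps": [r.n_snps for r in results],
            "n_skipped": [r.n_skipped for r in results],
            "mean_vst": [r.mean_vst for r in results],
            "raw_mean_vst": [r.raw_mean_vst for r in results],
            "threshold": [r.threshold_used for r in results],
            "rule": [r.rule for r in results],
            "significant": [r.significant for r in results],
            "sig_mean2sd": [r.flags.get("mean2sd") for r in results],
            "sig_top5pct": [r.flags.get("top5pct") for r in results],
        }
    )
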