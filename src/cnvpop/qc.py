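"""Per-sample signal quality metrics and the exclusion cascade.

Four metrics are computed from a sample's LRR track:

* call rate — fraction of probes with a non-missing value;
* DLRS (derivative log ratio spread) — SD of adjacent-probe LRR differences
  within chromosomes, pooled, divided by sqrt(2); a short-range noise gauge
  insensitive to genuine long CNVs;
* wave factor — Pearson correlation between LRR and probe GC fraction,
  capturing long-range GC-correlated waviness;
* LRR SD — plain standard deviation of the track.

The exclusion cascade applies, in order: call rate >= 0.98, DLRS not a
cohort outlier (mean + 3 SD by default), |wave factor| <= 0.10, and
LRR SD < 0.30; a sample is labeled with the first rule it fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cnvpop.io import SignalMatrix


class UndefinedMetricError(ValueError):
    """A metric has no value for this sample (e.g. all probes missing)."""


@dataclass
class QcThresholds:
    min_call_rate: float = 0.98
    max_lrr_sd: float = 0.30          # exclusive: kept samples have SD < 0.30
    dlrs_outlier_nsd: float = 3.0     # DLRS > cohort mean + nsd * SD excludes
    dlrs_cutoff: float | None = None  # explicit cutoff overrides the cohort rule
    max_abs_wave: float = 0.10
    dlrs_robust: bool = False         # MAD-based spread instead of plain SD


@dataclass
class SampleQcReport:
    sample_id: str
    call_rate: float
    dlrs: float
    wave_factor: float
    lrr_sd: float
    excluded: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)


def compute_dlrs(sample_lrr: np.ndarray, chroms: np.ndarray, robust: bool = False) -> float:
    """SD of within-chromosome first differences of LRR, divided by sqrt(2).

    Differences never span a chromosome boundary; pairs with a missing value
    drop out.  Sample SD uses the n-1 denominator.  With ``robust`` the SD is
    replaced by 1.4826 * MAD (consistent for a Gaussian).
    """
    sample_lrr = np.asarray(sample_lrr, dtype=float)
    chroms = np.asarray(chroms)
    diffs = []
    for chrom in pd.unique(chroms):
        vals = sample_lrr[chroms == chrom]
        if vals.size >= 2:
            d = np.diff(vals)
            diffs.append(d[~np.isnan(d)])
    if not diffs:
        raise UndefinedMetricError("no adjacent probe pairs available for DLRS")
    pooled = np.concatenate(diffs)
    if pooled.size < 2:
        raise UndefinedMetricError("fewer than two usable adjacent differences")
    if robust:
        spread = 1.4826 * np.median(np.abs(pooled - np.median(pooled)))
    else:
        spread = np.std(pooled, ddof=1)
    return float(spread / np.sqrt(2.0))


def compute_wave_factor(sample_lrr: np.ndarray, gc_frac: np.ndarray) -> float:
    """Pearson correlation of per-probe LRR against GC fraction (sign kept)."""
    sample_lrr = np.asarray(sample_lrr, dtype=float)
    gc_frac = np.asarray(gc_frac, dtype=float)
    ok = ~np.isnan(sample_lrr) & ~np.isnan(gc_frac)
    if ok.sum() < 3:
        raise UndefinedMetricError("fewer than three probes with LRR and GC")
    if np.ptp(gc_frac[ok]) == 0:
        raise UndefinedMetricError("gc_frac is constant; wave factor undefined")
    if np.ptp(sample_lrr[ok]) == 0:
        return 0.0
    r, _ = stats.pearsonr(sample_lrr[ok], gc_frac[ok])
    return float(r)


def compute_qc_reports(signal: SignalMatrix, robust_dlrs: bool = False) -> list[SampleQcReport]:
    """All four metrics for every sample of a signal matrix."""
    chroms = signal.chroms
    gc = signal.gc
    reports = []
    for j, sid in enumerate(signal.samples):
        lrr = signal.lrr[:, j]
        ok = ~np.isnan(lrr)
        reports.append(
            SampleQcReport(
                sample_id=sid,
                call_rate=float(ok.mean()),
                dlrs=compute_dlrs(lrr, chroms, robust=robust_dlrs),
                wave_factor=compute_wave_factor(lrr, gc),
                lrr_sd=float(np.std(lrr[ok], ddof=1)) if ok.sum() >= 2 else float("nan"),
            )
        )
    return reports


def apply_qc_filters(
    reports: list[SampleQcReport], thresholds: QcThresholds | None = None
) -> tuple[list[str], dict[str, str]]:
    """Partition samples into kept ids and {excluded id: first failing rule}.

    The DLRS outlier cutoff comes from the whole cohort's DLRS distribution
    before any exclusion, unless an explicit ``dlrs_cutoff`` is given (which
    also makes the cascade idempotent on the kept subset).  Reports are
    mutated in place with the exclusion flag and reasons.
    """
    th = thresholds or QcThresholds()
    if th.dlrs_cutoff is not None:
        dlrs_cut = th.dlrs_cutoff
    elif len(reports) >= 2:
        dlrs_values = np.asarray([r.dlrs for r in reports])
        dlrs_cut = dlrs_values.mean() + th.dlrs_outlier_nsd * dlrs_values.std(ddof=1)
    else:
        dlrs_cut = np.inf

    kept: list[str] = []
    excluded: dict[str, str] = {}
    for r in reports:
        reason = None
        if r.call_rate < th.min_call_rate:
            reason = "call_rate"
        elif r.dlrs > dlrs_cut:
            reason = "dlrs"
        elif abs(r.wave_factor) > th.max_abs_wave:
            reason = "wave_factor"
        elif not (r.lrr_sd < th.max_lrr_sd):
            reason = "lrr_sd"
        if reason is None:
            r.excluded = False
            r.exclusion_reasons = []
            kept.append(r.sample_id)
        else:
            r.excluded = True
            r.exclusion_reasons = [reason]
            excluded[r.sample_id] = reason
    return kept, excluded


def reports_to_frame(reports: list[SampleQcReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "call_rate": [r.call_rate for r in reports],
            "dlrs": [r.dlrs for r in reports],
            "wave_factor": [r.wave_factor for r in reports],
            "lrr_sd": [r.lrr_sd for r in reports],
            "excluded": [r.excluded for r in reports],
            "exclusion_reasons": [";".join(r.exclusion_reasons) for r in reports],
        }
    )
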