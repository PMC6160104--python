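"""Synthetic multi-breed cohort generator.

Emulates the data a high-density SNP array delivers for a CNV study: a probe
map with GC content, per-sample LRR (optionally BAF) signal, truth CNV calls,
a sample->population manifest and chromosome sizes.  Each population carries
each CNV template with its own carrier frequency, which is the lever that
creates population-differentiated regions for the V_ST scan and breed
clusters for the structure analyses.

Signal model per probe and sample::

    LRR = state_mean(tcn) + wave_amplitude * (gc - mean(gc)) + Normal(0, lrr_sd)

with ``state_mean(2) = 0`` for copy-neutral probes.  The GC term reproduces
the long-range "waviness" real arrays show; its amplitude is the per-sample
wave factor QC hunts for.  Samples are generated from independent substreams
derived from (seed, sample index), so enlarging a cohort never perturbs
earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cnvpop.io import CnvCall, SignalMatrix, SnpProbe, sort_probes

#: Conventional array LRR levels per total copy number.
_STATE_MEANS = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}

#: Canonical BAF cluster positions per total copy number (allele-ratio mixture).
_BAF_CLUSTERS = {
    0: (0.5,),               # no signal: BAF is noise around 0.5
    1: (0.0, 1.0),           # hemizygous: A or B only
    2: (0.0, 0.5, 1.0),
    3: (0.0, 1 / 3, 2 / 3, 1.0),
    4: (0.0, 0.25, 0.5, 0.75, 1.0),
}


def default_state_means() -> dict[int, float]:
    """LRR mean per TCN state; strictly increasing, 0 at the neutral state."""
    return dict(_STATE_MEANS)


@dataclass(frozen=True)
class CnvTemplate:
    """A CNV locus with per-population carrier frequencies."""

    chrom: str
    start: int
    end: int
    tcn: int
    carrier_freq: dict[str, float]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"template {self.chrom}:{self.start}-{self.end}: start > end")
        if self.tcn not in (0, 1, 3, 4):
            raise ValueError(f"template tcn must be in {{0,1,3,4}}, got {self.tcn}")
        for pop, freq in self.carrier_freq.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"carrier_freq[{pop!r}] = {freq} outside [0, 1]")


@dataclass
class SimulationConfig:
    populations: dict[str, int]
    templates: list[CnvTemplate] = field(default_factory=list)
    n_chrom: int = 2
    chrom_length_bp: int = 10_000_000
    n_probes_per_chrom: int = 500
    lrr_state_means: dict[int, float] = field(default_factory=default_state_means)
    lrr_sd: float = 0.20
    baf_model: bool = False
    baf_jitter_sd: float = 0.03
    wave_amplitude: float = 0.0
    call_rate_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations or any(n < 1 for n in self.populations.values()):
            raise ValueError("every population needs at least one sample")
        if self.lrr_sd <= 0:
            raise ValueError("lrr_sd must be > 0")
        means = [self.lrr_state_means[t] for t in sorted(self.lrr_state_means)]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("lrr_state_means must be strictly increasing in tcn")
        lo, hi = self.call_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("call_rate_range must satisfy 0 <= lo <= hi <= 1")


def _make_probe_map(config: SimulationConfig, rng: np.random.Generator) -> list[SnpProbe]:
    probes = []
    spacing = config.chrom_length_bp // (config.n_probes_per_chrom + 1)
    for c in range(1, config.n_chrom + 1):
        chrom = str(c)
        gc = rng.uniform(0.3, 0.7, size=config.n_probes_per_chrom)
        for j in range(config.n_probes_per_chrom):
            pos = (j + 1) * spacing
            probes.append(SnpProbe(f"snp_{chrom}_{j}", chrom, pos, float(gc[j])))
    return sort_probes(probes)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SnpProbe], SignalMatrix, list[CnvCall], dict[str, str], dict[str, int]]:
    """Simulate a cohort; returns (probe map, signal, truth calls, manifest, chrom sizes).

    Truth calls carry exact template bounds and the count of probes inside
    them.  Templates overlapping the same sample are applied independently;
    where two carried templates cover the same probe, the later template in
    the config wins that probe's state (templates are normally disjoint).
    """
    chrom_sizes = {str(c): config.chrom_length_bp for c in range(1, config.n_chrom + 1)}
    for t in config.templates:
        if t.chrom not in chrom_sizes or t.end > chrom_sizes[t.chrom] or t.start < 1:
            raise ValueError(
                f"template {t.chrom}:{t.start}-{t.end} outside chromosome bounds"
            )

    master = np.random.default_rng(config.seed)
    probes = _make_probe_map(config, master)
    chroms = np.asarray([p.chrom for p in probes])
    positions = np.asarray([p.pos for p in probes], dtype=np.int64)
    gc = np.asarray([p.gc_frac for p in probes])
    gc_centered = gc - gc.mean()

    # Probe index ranges per template, and per-template probe counts for calls.
    template_probe_idx = []
    for t in config.templates:
        mask = (chroms == t.chrom) & (positions >= t.start) & (positions <= t.end)
        template_probe_idx.append(np.flatnonzero(mask))

    manifest: dict[str, str] = {}
    sample_ids: list[str] = []
    for pop, n in config.populations.items():
        for i in range(n):
            sid = f"{pop}_{i:03d}"
            manifest[sid] = pop
            sample_ids.append(sid)

    means = config.lrr_state_means
    n_probes = len(probes)
    lrr = np.empty((n_probes, len(sample_ids)))
    baf = np.empty_like(lrr) if config.baf_model else None
    truth: list[CnvCall] = []

    for s_idx, sid in enumerate(sample_ids):
        pop = manifest[sid]
        rng = np.random.default_rng([config.seed, s_idx])
        tcn_per_probe = np.full(n_probes, 2, dtype=int)
        for t, idx in zip(config.templates, template_probe_idx):
            if rng.random() < t.carrier_freq.get(pop, 0.0):
                tcn_per_probe[idx] = t.tcn
                if idx.size >= 1:
                    truth.append(
                        CnvCall(sid, t.chrom, t.start, t.end, t.tcn, int(idx.size))
                    )
        state_mean = np.asarray([means[t] for t in tcn_per_probe])
        lrr[:, s_idx] = (
            state_mean
            + config.wave_amplitude * gc_centered
            + rng.normal(0.0, config.lrr_sd, size=n_probes)
        )
        if baf is not None:
            baf[:, s_idx] = _draw_baf(tcn_per_probe, rng, config.baf_jitter_sd)
        lo, hi = config.call_rate_range
        call_rate = rng.uniform(lo, hi)
        if call_rate < 1.0:
            missing = rng.random(n_probes) >= call_rate
            lrr[missing, s_idx] = np.nan
            if baf is not None:
                baf[missing, s_idx] = np.nan

    signal = SignalMatrix(probes=probes, samples=sample_ids, lrr=lrr, baf=baf)
    return probes, signal, truth, manifest, chrom_sizes


def _draw_baf(tcn_per_probe: np.ndarray, rng: np.random.Generator, jitter_sd: float) -> np.ndarray:
    out = np.empty(tcn_per_probe.shape, dtype=float)
    for tcn in np.unique(tcn_per_probe):
        idx = np.flatnonzero(tcn_per_probe == tcn)
        clusters = np.asarray(_BAF_CLUSTERS[int(tcn)])
        choice = rng.integers(0, len(clusters), size=idx.size)
        out[idx] = clusters[choice] + rng.normal(0.0, jitter_sd, size=idx.size)
    return np.clip(out, 0.0, 1.0)


def differentiated_pair_config(
    freq_gap: float,
    n_per_pop: int = 50,
    n_templates: int = 6,
    base_freq: float = 0.1,
    lrr_sd: float = 0.20,
    seed: int = 0,
    tcn: int = 1,
) -> SimulationConfig:
    """Two-population config whose templates differ in carrier frequency by ``freq_gap``.

    Population A carries each template at ``base_freq + freq_gap``, population
    B at ``base_freq``; templates are evenly spread over the simulated genome.
    Convenience builder for differentiation benchmarks.
    """
    if not 0.0 <= base_freq + freq_gap <= 1.0:
        raise ValueError("base_freq + freq_gap must stay in [0, 1]")
    config = SimulationConfig(
        populations={"A": n_per_pop, "B": n_per_pop},
        n_chrom=2,
        lrr_sd=lrr_sd,
        seed=seed,
    )
    spacing = config.chrom_length_bp // (config.n_probes_per_chrom + 1)
    templates = []
    per_chrom = (n_templates + config.n_chrom - 1) // config.n_chrom
    width = 20 * spacing  # ~20 probes per template
    for i in range(n_templates):
        chrom = str(1 + i // per_chrom)
        offset = (i % per_chrom) * (config.chrom_length_bp // per_chrom)
        start = offset + 5 * spacing
        templates.append(
            CnvTemplate(
                chrom=chrom, start=start, end=start + width, tcn=tcn,
                carrier_freq={"A": base_freq + freq_gap, "B": base_freq},
            )
        )
    config.templates = templates
    return config
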