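import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpop.cnvr import CnvRegion, merge_calls_to_regions
from cnvpop.matrix import build_matrix
from cnvpop.simulate import differentiated_pair_config, generate_cohort
from cnvpop.vst import UndefinedVstError, region_vst, snp_vst, vst_scan


def brute_vst(x1, x2):
    """Direct variance arithmetic, independent of the implementation path."""
    pooled = list(x1) + list(x2)
    mean = sum(pooled) / len(pooled)
    v_t = sum((v - mean) ** 2 for v in pooled) / len(pooled)
    m1, m2 = sum(x1) / len(x1), sum(x2) / len(x2)
    v1 = sum((v - m1) ** 2 for v in x1) / len(x1)
    v2 = sum((v - m2) ** 2 for v in x2) / len(x2)
    v_s = (len(x1) * v1 + len(x2) * v2) / (len(x1) + len(x2))
    return (v_t - v_s) / v_t


class TestSnpVst:
    def test_identical_populations_give_zero(self):
        x = [0.1, -0.2, 0.4, 0.0]
        clamped, raw = snp_vst(x, x)
        assert clamped == pytest.approx(0.0, abs=1e-12)
        assert raw == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_constant_signals_give_one(self):
        clamped, _ = snp_vst([0.4] * 5, [-0.6] * 7)
        assert clamped == 1.0

    def test_matches_brute_force_formula(self):
        x1, x2 = [0.0, 0.0, 0.2], [0.5, 0.7]
        clamped, raw = snp_vst(x1, x2)
        assert raw == pytest.approx(brute_vst(x1, x2))
        assert clamped == pytest.approx(max(0.0, min(1.0, brute_vst(x1, x2))))

    def test_zero_total_variance_returns_zero(self):
        assert snp_vst([0.3, 0.3], [0.3, 0.3]) == (0.0, 0.0)

    def test_equal_sizes_make_vs_the_plain_average(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=20), rng.normal(1, 2, size=20)
        _, raw = snp_vst(x1, x2)
        v1, v2 = np.var(x1), np.var(x2)
        v_t = np.var(np.concatenate([x1, x2]))
        assert raw == pytest.approx((v_t - (v1 + v2) / 2) / v_t)

    def test_too_few_values_raise(self):
        with pytest.raises(UndefinedVstError):
            snp_vst([0.1], [0.2, 0.3])

    def test_missing_values_dropped(self):
        clamped, _ = snp_vst([0.4, 0.4, np.nan], [-0.6, -0.6, np.nan])
        assert clamped == 1.0

    @given(shift=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_shift_and_label_swap_invariance(self, shift):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=10), rng.normal(0.5, 1.5, size=15)
        base = snp_vst(x1, x2)[1]
        assert snp_vst(x1 + shift, x2 + shift)[1] == pytest.approx(base, abs=1e-9)
        assert snp_vst(x2, x1)[1] == pytest.approx(base, abs=1e-12)


def _region(chrom, start, end):
    return CnvRegion(chrom, start, end, "loss", frozenset({"x"}))


class TestRegionVst:
    def _signal(self, templates_gap, **kwargs):
        config = differentiated_pair_config(templates_gap, **kwargs)
        return generate_cohort(config)

    def test_single_probe_region_equals_probe_value(self, two_pop_cohort):
        probes, signal, _, manifest, _ = two_pop_cohort
        probe = signal.probes[10]
        region = _region(probe.chrom, probe.pos, probe.pos)
        result = region_vst(region, signal, manifest, ("A", "B"))
        cols_a = [j for j, s in enumerate(signal.samples) if manifest[s] == "A"]
        cols_b = [j for j, s in enumerate(signal.samples) if manifest[s] == "B"]
        idx = signal.probes.index(probe)
        expected, _ = snp_vst(signal.lrr[idx, cols_a], signal.lrr[idx, cols_b])
        assert result.mean_vst == pytest.approx(expected)
        assert result.n_snps == 1

    def test_fully_differentiated_noise_free_region_is_one(self):
        config = differentiated_pair_config(1.0, base_freq=0.0, lrr_sd=1e-12, n_per_pop=5, seed=2)
        probes, signal, truth, manifest, _ = generate_cohort(config)
        t = config.templates[0]
        result = region_vst(_region(t.chrom, t.start, t.end), signal, manifest, ("A", "B"))
        assert result.mean_vst == pytest.approx(1.0, abs=1e-6)

    def test_region_without_probes_raises(self, two_pop_cohort):
        _, signal, _, manifest, _ = two_pop_cohort
        with pytest.raises(UndefinedVstError):
            region_vst(_region("1", 1, 2), signal, manifest, ("A", "B"))

    def test_differentiated_region_beats_null_percentile(self):
        # a carrier-frequency gap of 0.9 must push mean V_ST above the 99th
        # percentile of frequency-matched undifferentiated regions
        config = differentiated_pair_config(0.9, base_freq=0.0, n_per_pop=50, seed=3,
                                            n_templates=1)
        probes, signal, _, manifest, _ = generate_cohort(config)
        t = config.templates[0]
        hot = region_vst(_region(t.chrom, t.start, t.end), signal, manifest, ("A", "B")).mean_vst

        null_config = differentiated_pair_config(0.0, base_freq=0.45, n_per_pop=50, seed=4,
                                                 n_templates=1)
        null_values = []
        for rep in range(100):
            null_config.seed = 100 + rep
            _, null_signal, _, null_manifest, _ = generate_cohort(null_config)
            nt = null_config.templates[0]
            null_values.append(
                region_vst(_region(nt.chrom, nt.start, nt.end), null_signal,
                           null_manifest, ("A", "B")).mean_vst
            )
        assert hot > np.quantile(null_values, 0.99)


class TestVstScan:
    def _scan_inputs(self, seed=5, gap=0.6):
        config = differentiated_pair_config(gap, base_freq=0.2, n_per_pop=40, seed=seed)
        probes, signal, truth, manifest, _ = generate_cohort(config)
        regions = merge_calls_to_regions(truth)
        matrix = build_matrix(regions, truth, manifest, encoding="presence")
        return regions, signal, manifest, matrix

    def test_thresholds_match_direct_percentile_and_moments(self):
        regions, signal, manifest, matrix = self._scan_inputs()
        results = vst_scan(regions, signal, manifest, [("A", "B")],
                           carrier_counts=matrix.carrier_counts(manifest))
        means = np.array([r.mean_vst for r in results])
        assert results[0].threshold_used == pytest.approx(means.mean() + 2 * means.std(ddof=1))
        top5 = np.quantile(means, 0.95)
        for r in results:
            assert r.flags["top5pct"] == (r.mean_vst > top5)
            assert r.flags["mean2sd"] == (r.mean_vst > results[0].threshold_used)

    def test_outlier_region_flagged_under_both_rules(self):
        # 99 null-like values and one at 0.9: both rules must flag the outlier
        means = np.array([0.0] * 99 + [0.9])
        mean2sd = means.mean() + 2 * means.std(ddof=1)
        assert 0.9 > mean2sd
        assert 0.9 > np.quantile(means, 0.95)

    def test_identical_means_yield_no_mean2sd_hits(self):
        regions, signal, manifest, _ = self._scan_inputs()
        means = np.full(30, 0.2)
        assert not np.any(means > means.mean() + 2 * means.std(ddof=1))

    def test_three_populations_scan_pairwise(self):
        from cnvpop.simulate import CnvTemplate, SimulationConfig

        config = SimulationConfig(
            populations={"A": 20, "B": 20, "C": 20},
            n_chrom=1, chrom_length_bp=2_000_000, n_probes_per_chrom=200,
            seed=6,
            templates=[
                CnvTemplate("1", 100_000, 300_000, 1, {"A": 0.9, "B": 0.2, "C": 0.2}),
                CnvTemplate("1", 900_000, 1_100_000, 3, {"A": 0.5, "B": 0.5, "C": 0.5}),
            ],
        )
        _, signal, truth, manifest, _ = generate_cohort(config)
        regions = merge_calls_to_regions(truth)
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        results = vst_scan(regions, signal, manifest, pairs)
        assert {r.pair for r in results} == set(pairs)
        by_pair = {p: [r.mean_vst for r in results if r.pair == p] for p in pairs}
        # the differentiated locus separates A-pairs far more than B vs C
        assert max(by_pair[("A", "B")]) > 3 * max(by_pair[("B", "C")])

    def test_carrier_filter_applies_per_pair(self):
        regions, signal, manifest, matrix = self._scan_inputs()
        counts = matrix.carrier_counts(manifest)
        results = vst_scan(regions, signal, manifest, [("A", "B")],
                           min_carriers=5, carrier_counts=counts)
        scanned_ids = {r.region.region_id for r in results}
        for region in regions:
            eligible = (
                region.region_id in counts.index
                and counts.loc[region.region_id, "A"] >= 5
                and counts.loc[region.region_id, "B"] >= 5
            )
            assert (region.region_id in scanned_ids) == eligible

    def test_few_regions_warn_on_unstable_quantile(self):
        regions, signal, manifest, _ = self._scan_inputs()
        with pytest.warns(UserWarning, match="unstable"):
            vst_scan(regions[:2], signal, manifest, [("A", "B")])


def test_monotone_recovery_over_frequency_gaps():
    # mean V_ST at the differentiated locus must increase strictly with the
    # between-population carrier-frequency gap
    from scipy.stats import spearmanr

    gaps = [0.0, 0.3, 0.6, 0.9]
    curve = []
    for gap in gaps:
        config = differentiated_pair_config(gap, base_freq=0.05, n_per_pop=50,
                                            seed=7, n_templates=1)
        _, signal, _, manifest, _ = generate_cohort(config)
        t = config.templates[0]
        region = CnvRegion(t.chrom, t.start, t.end, "loss", frozenset({"x"}))
        curve.append(region_vst(region, signal, manifest, ("A", "B")).mean_vst)
    rho, _ = spearmanr(gaps, curve)
    assert rho == pytest.approx(1.0)
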