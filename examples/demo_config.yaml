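# Demo pipeline config: three simulated breeds with shared and
# breed-differentiated CNV loci.  Run with
#   cnvpop run --config examples/demo_config.yaml --out scratch/demo --seed 1
seed: 1

simulate:
  populations: {VRP: 24, IBS: 24, HOL: 24}
  n_chrom: 3
  chrom_length_bp: 10000000
  n_probes_per_chrom: 300
  lrr_sd: 0.20
  wave_amplitude: 0.0
  call_rate_range: [0.99, 1.0]
  templates:
    # shared across all three breeds
    - {chrom: "1", start: 500000, end: 1200000, tcn: 1,
       carrier_freq: {VRP: 0.6, IBS: 0.6, HOL: 0.6}}
    - {chrom: "2", start: 3000000, end: 3600000, tcn: 3,
       carrier_freq: {VRP: 0.5, IBS: 0.5, HOL: 0.5}}
    # Alpine-breed (VRP/IBS) enriched loci, rarer in HOL
    - {chrom: "1", start: 4000000, end: 4700000, tcn: 1,
       carrier_freq: {VRP: 0.8, IBS: 0.7, HOL: 0.25}}
    - {chrom: "3", start: 2000000, end: 2800000, tcn: 3,
       carrier_freq: {VRP: 0.7, IBS: 0.8, HOL: 0.25}}
    # HOL-enriched locus
    - {chrom: "2", start: 7000000, end: 7700000, tcn: 1,
       carrier_freq: {VRP: 0.25, IBS: 0.25, HOL: 0.8}}
    # VRP-specific locus
    - {chrom: "3", start: 6500000, end: 7200000, tcn: 4,
       carrier_freq: {VRP: 0.7, IBS: 0.25, HOL: 0.25}}
    # low-frequency background loci
    - {chrom: "1", start: 8000000, end: 8300000, tcn: 0,
       carrier_freq: {VRP: 0.2, IBS: 0.2, HOL: 0.2}}
    - {chrom: "2", start: 500000, end: 900000, tcn: 1,
       carrier_freq: {VRP: 0.25, IBS: 0.2, HOL: 0.25}}

qc:
  min_call_rate: 0.98
  max_lrr_sd: 0.30
  max_abs_wave: 0.10
  dlrs_outlier_nsd: 3.0

matrix:
  encoding: copy_number
  min_carriers: 5
  per_population: true

tree:
  bootstrap: 100
  metric: euclidean

vst:
  rule: mean2sd
  min_carriers: 5
  pairs: [[VRP, IBS], [VRP, HOL], [HOL, IBS]]
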