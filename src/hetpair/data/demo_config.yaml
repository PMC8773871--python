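# Demo run: one synthetic tumour pair with an APOBEC-divergent component,
# a planted CDH1 loss in the Neg component, one Neg subclone and planted
# discordant promoter probes. Filter thresholds are the published defaults:
# pop AF > 1% removed, VAF < 0.01 removed, depth >= 10 in both samples,
# tumour alt reads >= 5 and normal alt reads <= 2, synonymous removed.
seed: 0
tumour_id: DEMO1

simulation:
  n_mutations_total: 400
  trunk_fraction: 0.6
  signature_mixture:
    truncal: {SBS1: 0.5, SBS5: 0.5}
    Neg: {SBS2: 0.6, SBS13: 0.4}   # APOBEC-driven private mutations
    Abr: {SBS1: 0.6, SBS5: 0.4}    # clock-like private mutations
  purity: {Neg: 0.7, Abr: 0.6}
  mean_depth_tumour: 80
  mean_depth_normal: 40
  subclones:
    Neg: [[0.3, 120]]              # [cellular fraction, mutation count]
    Abr: []
  caller_profiles:
    callerA: {sensitivity: 0.95, false_positives: 5, vaf_noise_sd: 0.01}
    callerB: {sensitivity: 0.95, false_positives: 5, vaf_noise_sd: 0.01}
    callerC: {sensitivity: 0.90, false_positives: 5, vaf_noise_sd: 0.01}
  indel_fraction: 0.12
  n_contigs: 5
  contig_length: 200000
  n_genes: 40
  segment_length: 60000
  ploidy: {Neg: 2.0, Abr: 2.0}
  planted_cna:
    - {gene: CDH1, component: Neg, total_cn: 1, minor_cn: 0}
  n_probes: 2000
  discordant_probe_fraction: 0.02
  planted_promoter_methylation:
    - {gene: CTNNA1, component: Neg}

filters:
  pop_af_max: 0.01
  vaf_min: 0.01
  min_depth: 10
  depth_rule: both
  min_tumour_alt: 5
  max_normal_alt: 2

relatedness:
  related_min: 0.3
  independent_max: 0.1

subclone_k_max: 3
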