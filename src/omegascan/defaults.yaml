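# Versioned pipeline defaults. Every value can be overridden by a user
# config file; stage logic never hard-codes these.
seed: 0
log_level: INFO
threads: 1

paths:
  alignments: alignments          # directory of per-gene FASTA files
  tree: tree.nwk
  annotations: annotations.tsv
  memberships: null               # optional category->gene TSV; default: from annotations
  divergence_table: null          # optional externally produced divergence TSV

divergence:
  saturation_threshold: 1.0

windows:
  width: 0.001                    # dS units
  slide: 0.001
  percentile: 97.5
  min_genes: 40

paired:
  window_on: omega                # partner-species windowing axis: omega | dS

background:
  radius_bp: 100000
  ds_tolerance: 0.01

enrichment:
  underrepresentation: false

simulation:
  n_genes: 2000
  n_codons_min: 100
  n_codons_max: 500
  kappa: 2.0
  omega_median: 0.15
  omega_log_sd: 0.8
  gene_spacing: 12000
  rate_heterogeneity_shape: 3.0
  saturation_fraction: 0.03
  saturation_scale: 12.0
  terminal_length: 0.1
  internal_length: 0.05
  outgroup_length: 0.3
  category_sizes:
    SFP: 50
    Toll: 40
    JAK-STAT: 40
  branch_multipliers:
    SFP:
      nigrodunni: 10.0
      arawakana: 10.0
    Toll:
      arawakana: 10.0
    JAK-STAT:
      nigrodunni: 10.0
  chromosomes:
    - ["2L", 30000000]
    - ["2R", 30000000]
    - ["3L", 30000000]
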