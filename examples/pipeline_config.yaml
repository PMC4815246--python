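# Full-pipeline configuration for `dipseq run --config examples/pipeline_config.yaml`.
# Every key is optional; values shown are the defaults.

outdir: dipseq_run
seed: 0

# stage parameters
window: 1000          # segmentation window, bp
segment_fdr: 0.05     # Monte-Carlo empirical FDR target
iterations: 20        # randomization iterations
test: chisq           # chisq | negbin
q_threshold: 0.01     # DMR/DHMR call threshold on BH-adjusted p
overlap_window: 25000 # DMR-DHMR pairing distance, bp
overlap_method: hypergeom  # hypergeom | permutation
tss_flank: 1000       # TSS category half-width, bp
max_tss_distance: 50000
top_k: 2000           # regions annotated to genes, ranked by q
flank: 5000           # metagene flank, bp (500-bp bins)
body_bins: 40
heatmap_quantile: 0.8

# synthetic study (see SimulationConfig for the full list)
simulation:
  n_chroms: 2
  chrom_length: 5000000
  background_rate: 0.01   # tags per bp per library
  n_enriched: 100          # enriched domains per tissue x mark
  n_differential: 40       # of which differential at the fold below
  differential_fold: 3.0
  coupling: 0.5            # fraction of 5hmC diff regions near a 5mC partner
  coupled_pair: [down, up] # (5mC direction, 5hmC direction)
  replicates: 2
  tissues: [hippocampus, ventricle]
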