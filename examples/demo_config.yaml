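# Demo run at the study's design scale: 356 target + 63 essential genes at
# 4 guides/gene plus 324 NTC guides, one cell line, three arms grown for 15
# population doublings at 300x read depth per guide.  The first 20 target
# genes sensitize to both drugs (-0.5 log2/doubling); essentials drop out.
seed: 7
output_dir: screenkit_demo
cell_lines: [PCA1]
simulation:
  library:
    n_target_genes: 356
    n_essential_genes: 63
    n_ntc_guides: 324
    guides_per_gene: 4
  model:
    doublings: {DMSO: 15, OLA: 15, TALA: 15}
    depth_per_guide: 300
    dispersion: 100
    guide_efficiency: {alpha: 5, beta: 1}
    baseline_sigma: 0.5
    essential_fitness: -0.5
    sensitizers:
      OLA: {n: 20, effect: -0.5}
      TALA: {n: 20, effect: -0.5}
contrasts:
  # the fitness contrast keeps essential controls (exclude: []) so they
  # anchor the normZ scale; drug contrasts exclude them as in hit calling
  fitness: {label: DMSO_vs_T0, control: [T0], treated: [DMSO], exclude: []}
  drugs:
    - {label: OLA_vs_DMSO, control: [DMSO], treated: [OLA]}
    - {label: TALA_vs_DMSO, control: [DMSO], treated: [TALA]}
resampling: {n_rep: 100, group_size: 4}
nomination: {fdr_max: 0.1, require_fdr: false}
known_genes: [CHD1L, BRCA1, MUS81, RNASEH2A, XRCC1]
plots: true
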