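# Bundled synthetic experiment: a scaled-down version of the study
# design (full organellar gene sets, reduced nuclear set) that runs the
# whole pipeline in seconds.  Defaults not listed here are the
# study-scale settings in energyomics.synthetic.SimConfig.
sim:
  seed: 7
  n_genes_by_compartment:
    nuclear: 6000
    mitochondrial: 126
    chloroplast: 96
  n_proteins: 800
alpha: 0.001
fc_thresholds: [2.0, 1.5]
protein_alpha: 0.05
enrich_p_cutoff: 0.01
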