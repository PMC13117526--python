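# Bundled null demo: study-default synthetic trial with every treatment
# effect switched off.  All posterior probabilities of superiority should
# land well inside (0.02, 0.98) -- no spurious certainty.
synthesis:
  missing_rate: 0.0
  effect_lacnaa: 0.0
  eeg_recovery_shift: 0.0
  ihc_effects: {}
seed: 1
outdir: scratch/demo_null
markers: [NeuN]
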