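# Analysis configuration for the quickstart scenario.
threshold: 60.0      # binarization threshold T (per video)
background: 60.0     # the synthetic sheet's brightness level
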