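outdir = "report"
seed = 3

[simulate]
enabled = true
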