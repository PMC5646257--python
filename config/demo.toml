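seed = 0
output_dir = "straindrift_out"

[thresholds]
min_frequency = 0.10
high_frequency_cutoff = 0.80
max_strand_bias = 0.70

[criteria]
min_length = 1000
max_pI = 4.5
max_cysteines = 3

[reactor]
generation_time = 6.8
carrying_capacity = 400.0
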