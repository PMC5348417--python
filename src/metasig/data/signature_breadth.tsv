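direction	n_unique	n_reported_gt3
up	203	21
down	222	39
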