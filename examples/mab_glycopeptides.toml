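# Settings for labelled tryptic glycopeptide batches (HILIC-UPLC-FLR).
start_tr = 11.0
end_tr = 25.0
background_window = 1.0
baseline_order = 1
baseline_points = 100
min_calibrants = 4
min_sn = 9.0
cutoff_fraction = 0.01
quant_window = 0.15
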