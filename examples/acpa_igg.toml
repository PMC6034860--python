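# Settings for pre-calibrated labelled IgG glycan batches
# (run the batch without --calibrants; the exports are already aligned).
start_tr = 5.0
end_tr = 30.0
background_window = 1.0
baseline_order = 1
baseline_points = 100
min_calibrants = 4
min_sn = 27.0
cutoff_fraction = 0.01
quant_window = 0.2
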