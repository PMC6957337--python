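read_length: 100
min_fragment: 130
batches:
  batch1:
    insert_mean_log: 5.5215
    insert_sd_log: 0.25
  batch2:
    insert_mean_log: 5.7038
    insert_sd_log: 0.22
cleavage_rate:
  dtoxA:
    '0': 0.0
    '10': 0.5
    '30': 1.0
    '100': 2.0
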