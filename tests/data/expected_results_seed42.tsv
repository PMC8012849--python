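# format: nirsbmi-results
# seed: 42
# config_hash: 48c05264ee25da11
subject	accuracy_hbo	accuracy_hbr	accuracy_hbt	itr_hbo	itr_hbr
seed42	89.47	87.72	86.84	0.51	0.46
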