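group	molecule	viral_reads	total_reads
AMC	RNA	124803	132252624
AD	RNA	236939	158235930
AMC	DNA	124805	37225119
AD	DNA	146271	44743221
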