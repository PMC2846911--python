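#site_type five_prime
#intron_class U12_ATAC
#species synthetic
#exon_offset 3
2500 2500 2500 2500
2500 2500 2500 2500
2500 2500 2500 2500
8500 500 500 500
500 500 500 8500
8500 500 500 500
500 500 500 8500
500 8500 500 500
500 8500 500 500
500 500 500 8500
500 500 500 8500
500 500 500 8500
2500 2500 2500 2500
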