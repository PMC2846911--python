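#site_type three_prime
#intron_class U2_GTAG
#species synthetic
#exon_offset 3
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
2250 2750 2250 2750
5500 1500 1500 1500
1500 1500 5500 1500
1500 1500 5500 1500
2500 2500 2500 2500
2500 2500 2500 2500
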