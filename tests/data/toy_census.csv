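year,count
1925,2370
1926,2550
1927,2700
1928,2610
1929,2800
1930,3000
1931,3100
1932,2950
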