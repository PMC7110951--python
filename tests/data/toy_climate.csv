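year,winter_precip_mm
1926,420
1927,380
1928,510
1929,300
1930,450
1931,390
1932,480
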