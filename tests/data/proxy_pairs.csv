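year,station_avg_mm,snow_proxy_mm
1925,400,390
1926,350,370
1927,500,520
1928,450,400
1929,300,310
1930,420,405
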