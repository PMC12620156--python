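# Nine-peak liver triglyceride fat spectrum (water reference at 4.70 ppm).
# reference_temperature_celsius: 37
# Columns: chemical shift relative to water [ppm] (negative = upfield of
# water, main methylene peak at -3.40 ppm), relative amplitude (sums to 1).
0.59	0.0473
0.49	0.0146
-0.50	0.0387
-1.95	0.0064
-2.46	0.0584
-2.68	0.0643
-3.10	0.0596
-3.40	0.6206
-3.80	0.0901
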