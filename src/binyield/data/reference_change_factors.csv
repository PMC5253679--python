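crop,period,below30,f30_36,above36
maize,historical,1.80,0.73,0.96
maize,future,1.62,0.41,0.47
soybean,historical,2.84,0.88,0.95
soybean,future,2.12,0.71,0.59
wheat,historical,0.93,0.91,0.99
wheat,future,0.85,0.78,0.94
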