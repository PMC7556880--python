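>GBM_synthetic
0.10 0.10 0.70 0.10
0.70 0.10 0.10 0.10
0.05 0.85 0.05 0.05
0.05 0.85 0.05 0.05
0.985 0.005 0.005 0.005
0.05 0.85 0.05 0.05
0.05 0.85 0.05 0.05
0.10 0.60 0.10 0.20
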