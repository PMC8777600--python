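product_id,%R,%Q,%K
S1,11.67,5.05,9.62
S2,5.73,6.44,24.88
S3,4.03,29.13,21.36
S4,87.42,1.88,0.00
S5,3.16,3.96,11.36
S6,58.43,5.20,10.95
S7,3.99,26.91,13.80
S8,3.16,29.39,24.92
S9,5.51,24.38,3.07
S10,4.88,57.85,3.09
S11,8.77,30.98,28.64
S12,4.24,37.44,4.80
S13,4.33,22.85,9.76
S14,4.39,44.74,1.62
S15,6.26,48.57,2.30
S16,6.34,36.38,2.62
S17,2.95,28.35,18.93
S18,3.17,0.76,0.00
S19,86.52,0.00,0.00
S20,86.77,0.00,0.00
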