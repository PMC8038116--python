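fraction,mn_da,mw_da,mws_da,yield_percent
P0,17600,39300,168,100
P2,156500,240200,165,6.6
P3,46100,58600,171,19.8
P4,13200,14500,175,36.2
P5,7000,8700,163,25.2
P6,5600,14100,157,7.7
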