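linkage,P0,P3,P4,P5
t-Araf,12.6,13.7,10.4,15.0
t-Arap,0.3,0.2,0.3,0.9
2-Araf,0.5,0.8,0.4,1.8
3-Araf,4.5,6.8,3.1,5.2
5-Araf,12.4,12.6,6.5,12.5
"3,5-Araf",3.6,5.3,2.2,3.5
"2,5-Araf",1.7,2.5,1.0,1.7
"2,3,5-Araf",5.4,2.3,3.2,4.5
t-Galp,3.6,2.8,5.1,1.5
3-Galp,1.2,2.1,1.5,0.2
4-Galp,1.6,3.5,1.5,1.2
6-Galp,2.9,4.9,0.6,1.0
"4,6-Galp",0.7,0.9,0.7,0.6
"3,4-Galp",0.2,0.3,0.5,0.1
"3,6-Galp",1.2,0.9,0.7,1.2
t-GalpA,2.5,0.4,1.5,2.1
4-GalpA,21.4,19.1,36.4,28.4
"3,4-GalpA",1.7,1.4,2.5,0.0
t-Rhap,0.6,0.2,0.4,1.8
2-Rhap,2.2,3.4,3.5,0.0
"2,4-Rhap",4.5,6.9,4.7,2.4
t-Glcp,2.0,0.2,0.9,2.6
4-Glcp,2.9,2.4,3.8,2.6
"4,6-Glcp",2.7,1.4,2.3,0.2
t-Xylp,1.4,0.6,1.2,0.8
4-Xylp,2.0,0.6,1.3,5.4
4-Manp,4.0,3.2,3.3,2.3
"4,6-Manp",0.7,0.0,0.0,0.3
t-GlcpA,0.3,0.4,0.4,0.0
4-GlcpA,0.1,0.2,0.1,0.0
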