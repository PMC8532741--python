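id,name,h_score
20,Bella,0.34
21,Dream,0.1
22,Gino,0.86
23,Brutus,0.08
24,Waaly,0.02
25,Theresa,0.26
26,Belle,0.35
27,Jema,0.01
28,Laila,0.05
29,Ketem,0.26
30,Sparki,0.22
31,Boby,0.07
32,Ringo,0.42
33,Mika,0.87
34,Pie,0.02
35,Mila,0.61
36,Chelsee,0.25
37,Pachita,0.63
38,Pit.,0.99
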