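id,name,visit,h_score,medication,b_mod,tbv_months
1,Pery,first,0.73,Fluoxetine 80 mg,+,
1,Pery,follow-up,0.01,,,2
5,Indi,first,0.91,Fluoxetine 60 mg,-,
5,Indi,follow-up,0.82,,,2
6,Dafi,first,0.96,Fluoxetine 50 mg,+,
6,Dafi,follow-up,0.25,,,2
7,Bana,first,0.7,Fluoxetine 50 mg,-,
7,Bana,follow-up,0.26,,,2
16,Kim,first,0.97,Fluexetine 60 mg,+,
16,Kim,follow-up,0.67,,,1
18,Henri,first,0.97,Fluoxetine 20 mg + Trazodone 25 mg,+,
18,Henri,follow-up,0.86,,,2
4,Humus,first,0.2,Fluoxetine 70 mg,+,
4,Humus,follow-up,0.02,,,2
12,Nancy,first,0.25,Fluoxetine 60 mg,+,
12,Nancy,follow-up,0.01,,,2
10,Lichi,first,1,Fluoxetine 60 mg,+,
10,Lichi,follow-up,1,Fluoxetine 70 mg + Cyproterone Acetate 100 mg,,2
14,Angy L.,first,0.99,Fluoxetine 40 mg,-,
14,Angy L.,follow-up,0.99,Fluoxetine 40 mg,,2
11,Tomy,first,0.45,Fluoxetine 40 mg + Cyproterone Acetate 50 mg,-,
11,Tomy,follow-up,0.54,Fluoxetine 40 mg + Cyproterone Acetate 50 mg,,2
2,Patrick,first,0.98,Fluoxetine 90 mg,-,
3,Delpi,first,0.36,Fluoxetine 80 mg,+,
8,Guizmo,first,1,Fluoxetine 40 mg,-,
9,Max,first,0.63,,-,
13,Angy K.,first,0.89,Fluoxetine 30 mg,-,
15,Pit,first,1,Fluoxetine 80 mg,+,
17,Sia,first,1,Fluoxetine 60 mg + Trazodone 75 mg,+,
19,Mitch,first,1,Fluoxetine 40 mg,-,
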