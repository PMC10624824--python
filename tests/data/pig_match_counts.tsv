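chromosome	match	mismatch
1	270633269	539424
2	146662781	420263
3	130937868	425642
4	128427692	307617
5	101619062	362037
6	167000026	484255
7	118773752	380777
8	136957235	413526
9	136660501	463160
10	67560251	274356
11	77680673	301752
12	59493038	243072
13	204720959	496915
14	139462466	312847
15	138110563	310005
16	78160757	283293
17	61528660	207843
18	55233540	141756
X	112703361	125226
Y	6767646	1878658
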