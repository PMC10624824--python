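chromosome	ratio
1	0.998
2	0.997
3	0.997
4	0.998
5	0.996
6	0.997
7	0.997
8	0.997
9	0.997
10	0.996
11	0.996
12	0.996
13	0.998
14	0.998
15	0.998
16	0.996
17	0.997
18	0.997
X	0.999
Y	0.783
Total	0.996
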