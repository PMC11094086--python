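pos	A	C	G	U
1	0.15	0.3	0.15	0.4
2	0.1	0.35	0.1	0.45
3	0.05	0.1	0.05	0.8
4	0.94	0.02	0.02	0.02
5	0.08	0.45	0.07	0.4
6	0.25	0.25	0.25	0.25
7	0.25	0.25	0.25	0.25
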