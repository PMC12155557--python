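embryo_id	grade	day	te_label	te_profile	te_size_mb	icm_label	icm_profile	size_anomaly
1	4BB		Seg-A	gain 6q13~27.	80	EU	Euploidy
2	5BB		Seg-A	loss 6q25.3~27.	50	EU	Euploidy
3	5BB		Seg-A	gain 6q15~27.	60	EU	Euploidy
4	4AA		Seg-A	loss 7p22.3~15.1.	30	EU	Euploidy
5	3AB		Seg-A	gain 11p15.5~15.2.	15	EU	Euploidy
6	4AB		Seg-A	loss 13q31.1~34.	25	EU	Euploidy
7	5BB		Seg-A	gain 16p13.3~12.3.	10	EU	Euploidy
8	5BB		Seg-A	gain 1q12~44.	130	Seg-M	Mosaicism, XY; 30% mosaic gain of 11p11.2~q12.2; 30% mosaic loss of 1q21.2~44
9	4BB		Seg-A	gain 1q32.1~44.	95	Seg-M	Mosaicism, XX; 30% mosaic gain of 8q24.12~24.3; 30% mosaic loss of 2q32.1~37.3 and 9p24.3~21.1
10	5BB		Seg-A	gain 4p14~q13.1.	140	Seg-M	Mosaicism, XY; 40% mosaic loss of 5p15.33~15.2; 30% mosaic loss of 2p25.3~23.3
11	5CB		Seg-A	loss 4q31.3~35.2.	50	Seg-M	Mosaicism, XY; 60% mosaic loss of 4q31.3~4q35.2; 30% mosaic loss of 10q26.13~10q26.3
12	5BC		Seg-A	loss 5q12.1~14.1.	15	Seg-M	Mosaicism, XX; 80% mosaic loss of 5q12.1~14.1
13	5BC		Seg-A	loss 6p25.3~21.33.	20	Seg-M	Mosaicism, XX; 50% mosaic loss of 6p25.3~6p21.33, 6q26~6q27; 30% mosaic loss of 2p25.3~2p24.1
14	5BB		Seg-A	loss 6q25.3~27.	50	Seg-M	Mosaicism, XY; 30% mosaic loss of chr6
15	5BB		Seg-A	gain 7q21.12~36.3.	35	Seg-M	Mosaicism, XX; 30% mosaic gain of 11q24.2~25
16	4BB		Seg-A	loss 7q33~36.3	23	Seg-M	Mosaicism, XX; 80% mosaic loss of 7q33~36.3
17	5BC		Seg-A	loss 7q31.31~36.3.	10	Seg-M	Mosaicism, XY; 60% mosaic gain of 7q31.1~31.31; 60% mosaic loss of 7q31.31~36.3
18	5BA		Seg-A	gain 8q22.1~24.3.	40	Seg-M	Mosaicism, XY; 40% mosaic loss of 5p15.33~15.2, 6q26~27; 30% mosaic gain of 19p13.3~12; 30% mosaic loss of 14q32.12~32.33
19	5BB		Seg-A	gain 9p24.3~23.	20	Seg-M	Mosaicism, XY; 30% mosaic loss of 9p24.3~23
20	4BB		Seg-A	gain 12q13.11~24.33.	60	Seg-M	Mosaicism, XX; 30% mosaic loss of 5p15.33~15.2, 7q35~36.3, 13q33.1~34
21	3BB		Seg-A	gain 13q12.11~21.32.	30	Seg-M	Mosaicism, XY; 40% mosaic loss of 13q21.32~34; 30% mosaic gain of 19p13.3~12
22	3BB		Seg-A	gain 16p13.3~q11.2.	63	Seg-M	Mosaicism, XX; 80% mosaic gain of 16p13.3~q11.2
23	5BA		Seg-A	gain 18p11.32~q11.2	45	Seg-M	Mosaicism, XY; 30% mosaic gain of 19q13.11~13.42, 19p13.3~12; 30% mosaic loss of 2p25.3~24.1
24	4BA		Seg-A	gain 22q12.2~13.33.	10	Seg-M	Mosaicism, XY; 30% mosaic loss of 5p15.33~15.1
25	4BB		Seg-A	loss Xp22.33~11.3.	25	Seg-M	Mosaicism, XX; 60% mosaic loss of Xp22.33~Xp11.3; 30% mosaic gain of 4p16.1~14 and 19p13.3~13.11)
26	4BB		Seg-A	loss 3p26.3~14.1.	35	Seg-A	Aneuploidy, XY; loss 3p26.3~14.1.
27	3BB		Seg-A	loss 4q22.3~35.2.	75	Seg-A	Aneuploidy, XX; loss 4q22.2~35.2.
28	5BB		Seg-A	loss 5q34~35.3.	10	Seg-A	Aneuploidy, XY; loss 5q34~35.3.
29	5BB		Seg-A	loss 8q21.11~24.3.	30	Seg-A	Aneuploidy, XX; gain 3q27.3~3q29, loss 8q21.11~24.3.
30	5BC		Seg-A	loss 8q24.12~24.3.	10	Seg-A	Aneuploidy, XX; loss 8q24.12~24.3.
31	6BB		Seg-A	loss 12p13.33~11.21.	35	Seg-A	Aneuploidy, XY; loss 12p13.33~11.21.
32	5BB		Seg-A	loss 17q22~24.3.	20	Seg-A	Aneuploidy, XY; loss 17q22~24.3.
33	5BC		Seg-A	loss 18q22.1~23.	10	Seg-A	Aneuploidy, XY; loss 18q22.1~23.
34	5BC		Seg-A	loss Xq25~28.	20	Seg-A	Aneuploidy, XX; loss Xq25~28.
35	5BB		Seg-A	loss 4q25~35.2.	60	Who-A	Aneuploidy, XY; loss chr 4.
36	5BA		Seg-A	gain 14q23.2~24.3, loss 21q22.11~22.3.	1010	Who-A	Aneuploidy, XY; loss chr21.	size
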