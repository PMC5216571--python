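symbol	protein_id	rpkm_paternal	rpkm_hybrid	rpkm_maternal	category
cds2	ENSDARP00000003167	1.28	0.05	0.09	IX
foxj2	ENSDARP00000074846	10.44	4.68	2.00	XI
bmp2a	ENSDARP00000013686	4.94	1.97	0.59	XI
bambia	ENSDARP00000072198	6.95	1.36	3.51	III
insra	ENSDARP00000023951	2.24	8.00	3.67	IV
sall1a	ENSDARP00000102655	2.97	1.31	1.07	IX
ppm1bb	ENSDARP00000011459	2.40	0.16	0.42	I
fgf13b	ENSDARP00000003654	9.23	0.88	0.57	IX
suv420h2	ENSDARP00000106837	0.15	1.88	5.17	XII
cyr61l2	ENSDARP00000111890	0.62	2.54	7.51	XII
nrp1b	ENSDARP00000089039	2.43	1.83	7.18	VIII
skia	ENSDARP00000091440	2.78	2.76	7.82	VIII
vegfaa	ENSDARP00000110575	0.48	1.19	5.87	XII
crim1	ENSDARP00000050533	3.95	2.63	0.71	VII
pdgfrb	ENSDARP00000028652	17.97	7.00	2.72	XI
rhbdf1	ENSDARP00000053094	3.57	1.61	0.63	XI
smad1	ENSDARP00000030150	4.56	1.24	6.39	III
spry2	ENSDARP00000052422	5.17	1.31	0.49	XI
gna13b	ENSDARP00000036006	3.67	2.64	0.89	VII
si:dkey-101k6.5	ENSDARP00000071913	3.91	1.09	1.44	IX
smad9	ENSDARP00000031108	6.34	1.10	3.85	III
flt1	ENSDARP00000002466	0.20	2.85	6.13	XII
extl3	ENSDARP00000032226	8.98	3.64	3.80	IX
gpc4	ENSDARP00000007058	1.31	3.00	4.18	X
igfbp2b	ENSDARP00000019643	23.24	54.31	25.38	IV
tgfbr2	ENSDARP00000039831	2.31	2.47	6.37	VIII
igfbp5a	ENSDARP00000057368	0.02	4.36	2.07	VI
spred1	ENSDARP00000060763	8.41	2.71	2.02	IX
gdf2	ENSDARP00000076657	5.77	5.22	1.11	VII
fgf19	ENSDARP00000076455	5.53	1.00	1.56	IX
mdkb	ENSDARP00000018513	0.32	1.72	7.99	XII
insrb	ENSDARP00000096601	10.28	3.34	2.55	IX
igf2b	ENSDARP00000047568	30.01	25.43	11.67	VII
tgfb3	ENSDARP00000025519	5.09	1.37	1.12	IX
igfbp1b	ENSDARP00000056452	0.06	0.01	17.17	II
dusp22b	ENSDARP00000058288	2.73	3.92	8.08	VIII
tgif1	ENSDARP00000076869	1.53	3.92	4.53	X
rabep1	ENSDARP00000103673	1.63	2.82	8.90	VIII
igf1	ENSDARP00000017449	21.24	53.65	19.72	IV
ctnnb1	ENSDARP00000032935	3.94	1.69	0.73	XI
fgfr2	ENSDARP00000075360	5.09	2.16	6.13	III
bmpr2b	ENSDARP00000008469	1.43	1.84	7.07	VIII
pink1	ENSDARP00000014981	1.46	3.34	6.61	X
gdf6a	ENSDARP00000069999	0.67	0.65	0.09	VII
smad7	ENSDARP00000024277	5.83	18.91	19.20	X
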