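# 79 overlapping 15-mer peptides tiling the mature beta-2 glycoprotein I
# sequence (326 aa). Coordinates are 1-based inclusive. Domain labels use
# "k-k+1" for peptides spanning an inter-domain boundary.
peptide_number	sequence	start	end	domain
1	GRTCPKPDDLPFSTV	1	15	1
2	PKPDDLPFSTVVPLK	5	19	1
3	DLPFSTVVPLKTFYE	9	23	1
4	STVVPLKTFYEPGEE	13	27	1
5	PLKTFYEPGEEITYS	17	31	1
6	FYEPGEEITYSCKPG	21	35	1
7	GEEITYSCKPGYVSR	25	39	1
8	TYSCKPGYVSRGGMR	29	43	1
9	KPGYVSRGGMRKFIC	33	47	1
10	VSRGGMRKFICPLTG	37	51	1
11	GMRKFICPLTGLWPI	41	55	1
12	FICPLTGLWPINTLK	45	59	1
13	LTGLWPINTLKCTPR	49	63	1-2
14	WPINTLKCTPRVCPF	53	67	1-2
15	TLKCTPRVCPFAGIL	57	71	1-2
16	TPRVCPFAGILENGA	61	75	1-2
17	CPFAGILENGAVRYT	65	79	2
18	GILENGAVRYTTFEY	69	83	2
19	NGAVRYTTFEYPNTI	73	87	2
20	RYTTFEYPNTISFSC	77	91	2
21	FEYPNTISFSCNTGF	81	95	2
22	NTISFSCNTGFYLNG	85	99	2
23	FSCNTGFYLNGADSA	89	103	2
24	TGFYLNGADSAKCTE	93	107	2
25	LNGADSAKCTEEGKW	97	111	2
26	DSAKCTEEGKWSPEL	101	115	2
27	CTEEGKWSPELPVCA	105	119	2
28	GKWSPELPVCAPIIC	109	123	2-3
29	PELPVCAPIICPPPS	113	127	2-3
30	VCAPIICPPPSIPTF	117	131	2-3
31	IICPPPSIPTFATLR	121	135	3
32	PPSIPTFATLRVYKP	125	139	3
33	PTFATLRVYKPSAGN	129	143	3
34	TLRVYKPSAGNNSLY	133	147	3
35	YKPSAGNNSLYRDTA	137	151	3
36	AGNNSLYRDTAVFEC	141	155	3
37	SLYRDTAVFECLPQH	145	159	3
38	DTAVFECLPQHAMFG	149	163	3
39	FECLPQHAMFGNDTI	153	167	3
40	PQHAMFGNDTITCTT	157	171	3
41	MFGNDTITCTTHGNW	161	175	3
42	DTITCTTHGNWTKLP	165	179	3
43	CTTHGNWTKLPECRE	169	183	3
44	GNWTKLPECREVKCP	173	187	3-4
45	KLPECREVKCPFPSR	177	191	3-4
46	CREVKCPFPSRPDNG	181	195	3-4
47	KCPFPSRPDNGFVNY	185	199	4
48	PSRPDNGFVNYPAKP	189	203	4
49	DNGFVNYPAKPTLYY	193	207	4
50	VNYPAKPTLYYKDKA	197	211	4
51	AKPTLYYKDKATFGC	201	215	4
52	LYYKDKATFGCHDGY	205	219	4
53	DKATFGCHDGYSLDG	209	223	4
54	FGCHDGYSLDGPEEI	213	227	4
55	DGYSLDGPEEIECTK	217	231	4
56	LDGPEEIECTKLGNW	221	235	4
57	EEIECTKLGNWSAMP	225	239	4
58	CTKLGNWSAMPSCKA	229	243	4
59	GNWSAMPSCKASCKV	233	247	4-5
60	AMPSCKASCKVPVKK	237	251	4-5
61	CKASCKVPVKKATVV	241	255	4-5
62	CKVPVKKATVVYQGE	245	259	5
63	VKKATVVYQGERVKI	249	263	5
64	TVVYQGERVKIQEKF	253	267	5
65	QGERVKIQEKFKNGM	257	271	5
66	VKIQEKFKNGMLHGD	261	275	5
67	EKFKNGMLHGDKVSF	265	279	5
68	NGMLHGDKVSFFCKN	269	283	5
69	HGDKVSFFCKNKEKK	273	287	5
70	VSFFCKNKEKKCSYT	277	291	5
71	CKNKEKKCSYTEDAQ	281	295	5
72	EKKCSYTEDAQCIDG	285	299	5
73	SYTEDAQCIDGTIEV	289	303	5
74	DAQCIDGTIEVPKCF	293	307	5
75	IDGTIEVPKCFKEHS	297	311	5
76	IEVPKCFKEHSSLAF	301	315	5
77	KCFKEHSSLAFWKTD	305	319	5
78	EHSSLAFWKTDASDV	309	323	5
79	SLAFWKTDASDVKPC	312	326	5
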