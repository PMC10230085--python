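transcript_id	group	gene	accession	cv_percent
c35016_g13_i1	Nervous	Ov-Gsk3b	MW800694	3.89
c34071_g2_i1	Nervous	Ov-mts	MW800693	4.27
c30725_g11_i1	Nervous	Ov-timm	MW800652	4.40
c36083_g5_i1	Nervous	Ov-SUCLG2	MW800659	4.52
c33604_g6_i1	Nervous	Ov-CHCHD7	MW800655	4.63
c32222_g5_i1	Nervous	Ov-UBE2F	MW800681	5.16
c34932_g8_i1	Nervous	Ov-MTX1	MW800712	5.19
c31554_g1_i3	Nervous	Ov-gk5	MW800648	5.74
c35771_g14_i2	Nervous	Ov-Gnaq	MW800695	5.92
c35786_g9_i1	Nervous	Ov-Naa15	MW800658	6.35
c30400_g11_i1	Nervous	Ov-wdr44	MW800651	6.97
c17784_g1_i1	Nervous	Ov-Klhdc	MW800649	6.98
c35707_g2_i1	Nervous	Ov-PRMT5	MW800660	7.15
c32096_g14_i2	Nervous	Ov-Canx	MW800654	7.33
c35499_g5_i1	Nervous	Ov-ube2c	MW800657	7.79
c33913_g6_i1	Nervous	Ov-PTPN12	MW800656	9.22
c31227_g1_i2	Nervous	Ov-tollip	MW800653	9.24
c31322_g1_i1	Nervous	Ov-prrc1	MW800647	9.63
c28856_g1_i2	Nervous	Ov-CUL1	MW800650	9.91
c32222_g5_i1	Adult	Ov-UBE2F	MW800681	8.81
c35707_g2_i1	Adult	Ov-PRMT5	MW800660	10.25
c25466_g1_i1	Adult	Ov-Ltv1	MW800662	11.27
c35311_g1_i1	Adult	Ov-CPIJ005834	MW800676	12.23
c35010_g2_i4	Adult	Ov-EIF2A	MW800674	12.66
c29044_g1_i1	Adult	Ov-rpf1	MW800663	12.73
c31610_g1_i1	Adult	Ov-slc25a40	MW800667	12.79
c33222_g7_i1	Adult	Ov-RIOK2	MW800670	12.85
c32170_g13_i2	Adult	Ov-Dap3	MW800668	12.87
c34313_g4_i1	Adult	Ov-Ppm1b	MW800677	14.23
c34059_g14_i1	Adult	Ov-ATPAF2	MW800671	14.36
c30066_g9_i1	Adult	Ov-NOB1	MW800666	14.38
c32751_g1_i1	Adult	Ov-flr	MW800669	15.29
c34776_g5_i1	Adult	Ov-usp10	MW800673	15.39
c35032_g7_i2	Adult	Ov-Dnaja3	MW800675	15.61
c34087_g16_i1	Adult	Ov-CSDE1	MW800672	15.63
c29524_g1_i1	Adult	Ov-EIF3M	MW800665	15.71
c36175_g1_i1	Adult	Ov-BTBD17	MW800661	15.76
c29430_g1_i1	Adult	Ov-CG9286	MW800664	16.21
c34939_g11_i1	Arm	Ov-ESR16	MW800722	3.38
c35194_g4_i2	Arm	Ov-C2CD2	MW800723	3.69
c32350_g3_i1	Arm	Ov-nAChRalpha1	MW800709	3.71
c29941_g6_i1	Arm	Ov-14-3-3zeta	MW800678	4.27
c36050_g13_i1	Arm	Ov-Sdhd	MW800689	5.11
c34295_g8_i1	Arm	Ov-Vbp1	MW800685	5.33
c34563_g2_i1	Arm	Ov-PCK1	MW800686	5.51
c35194_g4_i1	Arm	Ov-C2CD2	MW800687	5.53
c35789_g7_i1	Arm	Ov-MRM2	MW800688	6.77
c32876_g12_i1	Arm	Ov-RNF7	MW800710	6.90
c30691_g3_i1	Arm	Ov-RSU1	MW800679	7.13
c31105_g4_i1	Arm	Ov-BTBD2	MW800680	7.22
c26803_g1_i1	Arm	Ov-RAD23B	MW800690	7.25
c28934_g1_i1	Arm	Ov-UGP2	MW800692	7.39
c28702_g2_i1	Arm	Ov-Abhd18	MW800691	8.08
c33117_g3_i1	Arm	Ov-Rnd3	MW800683	8.09
c32876_g7_i5	Arm	Ov-KCMF1	MW800682	9.26
c33305_g9_i1	Arm	Ov-Abi2	MW800684	10.22
c32222_g5_i1	Arm	Ov-UBE2F	MW800681	11.77
c34071_g2_i1	Brain	Ov-mts	MW800693	0.43
c28771_g3_i1	Brain	Ov-AP5Z1	MW800696	0.99
c34716_g8_i1	Brain	Ov-USP15	MW800700	1.29
c35771_g14_i2	Brain	Ov-Gnaq	MW800695	1.60
c35361_g5_i1	Brain	Ov-Fam160a2	MW800703	1.93
c34932_g8_i1	Brain	Ov-MTX1	MW800712	2.14
c34844_g11_i1	Brain	Ov-WBP2	MW800701	2.39
c30165_g11_i1	Brain	Ov-wls	MW800721	3.05
c31295_g14_i1	Brain	Ov-AP1M1	MW800711	3.05
c35016_g13_i1	Brain	Ov-Gsk3b	MW800694	3.19
c35896_g5_i1	Brain	Ov-Snx25	MW800705	3.36
c35327_g8_i2	Brain	Ov-FBXO38	MW800708	3.53
c35373_g3_i2	Brain	Ov-Snx20	MW800704	3.65
c30947_g6_i1	Brain	Ov-syvn1	MW800698	3.85
c32955_g4_i1	Brain	Ov-Homer2	MW800699	4.14
c35037_g6_i2	Brain	Ov-PIP4K2B	MW800702	4.94
c34087_g16_i1	Brain	Ov-CSDE1	MW800672	5.09
c36137_g10_i4	Brain	Ov-AGL	MW800706	5.44
c29565_g1_i1	Brain	Ov-CERK	MW800697	5.52
c34695_g13_i5	Brain	Ov-CNBP	MW800707	5.96
c26807_g1_i1	Published	Ov-eef1a	MW800714	16.81
c2281_g1_i1	Published	Ov-Rpl6	MW800718	24.75
c5816_g1_i1	Published	Ov-Rps27a	MW800713	30.40
c29373_g3_i1	Published	Ov-RPS18	MW800720	33.43
c12855_g1_i1	Published	Ov-TUBG1	MW800715	36.73
c34110_g1_i1	Published	Ov-MRPS5	MW800716	38.56
c30772_g3_i11	Published	Ov-RpL23	MW800719	42.20
c36025_g3_i2	Published	Ov-Tuba1a	MW800717	80.40
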