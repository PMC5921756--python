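name	locus_id	protein_id	chromosome	start	end	strand	protein_length	pi	mol_wt_kda	exon_count	isoform_count
CaARF1	LOC101492112	XP_004485416	Ca1	154447	160822	+	670	5.63	74.764	15	2
CaARF2	LOC101513952	XP_004485844	Ca1	2832460	2837619	-	711	6.33	77.719	12	3
CaARF3	LOC101501408	XP_004485979	Ca1	3851446	3857899	-	908	6.17	100.502	14	1
CaARF4	LOC101509547	XP_004487099	Ca1	12145610	12149407	+	719	8.56	79.314	5	3
CaARF5	LOC101492916	XP_012571810	Ca1	12333186	12338793	+	826	6.69	92.462	12	1
CaARF6	LOC101498659	XP_004488112	Ca1	24068315	24076322	-	1120	6.07	125.619	14	3
CaARF7	LOC101504978	XP_004490754	Ca2	28016288	28024622	-	833	5.89	92.432	14	1
CaARF8	LOC101503141	XP_004490828	Ca2	29095001	29096913	+	504	6.63	55.295	2	1
CaARF9	LOC101491204	XP_012568938	Ca3	14022096	14027221	+	671	5.89	75.111	3	1
CaARF10	LOC101505543	XP_004497510	Ca4	20116751	20120816	-	692	7.05	77.313	4	1
CaARF11	LOC101509304	XP_012570835	Ca4	48380932	48386526	-	917	5.55	102.376	15	1
CaARF12	LOC101496441	XP_012571326	Ca5	27748317	27758333	-	853	5.95	94.344	16	2
CaARF13	LOC101504083	XP_004503553	Ca6	4214355	4221885	+	1120	6.41	123.626	14	2
CaARF14	LOC101498188	XP_004503803	Ca6	6141652	6146690	-	867	6.09	96.712	14	1
CaARF15	LOC101500671	XP_004504542	Ca6	12432295	12439057	+	918	6.17	102.686	14	2
CaARF16	LOC101493974	XP_004505103	Ca6	17365769	17371522	-	725	6.32	80.25	10	2
CaARF17	LOC101505359	XP_012572776	Ca6	27667714	27674248	-	807	6.53	89.683	12	2
CaARF18	LOC101492451	XP_004506012	Ca6	28196797	28201150	-	706	7.03	78.446	4	1
CaARF19	LOC101515039	XP_012572936	Ca6	41935507	41941343	+	691	6.23	76.888	16	1
CaARF20	LOC101489666	XP_004508019	Ca7	3353577	3360886	-	1125	6.53	126.203	15	7
CaARF21	LOC101514738	XP_004510646	Ca7	34898868	34902262	+	612	7.61	69.328	4	2
CaARF22	LOC101492136	XP_004510662	Ca7	35086399	35091870	-	679	6.38	75.972	15	3
CaARF23	LOC101505502	XP_004511136	Ca7	44457833	44469177	+	444	5.72	50.687	12	1
CaARF24	LOC101514889	XP_012567350	UNPLACED			.	598	6.17	65.776	4	1
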