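spectrum_id	accession	protein_name	peptide	glycan	score	ratio_144_138	predicted_hexnac
scan=9001	Q12830	Nucleosome-remodeling factor subunit BPTF	TVITEVTTMTSTVATESK	N1	457	0.17	GlcNAc
scan=9002	Q96HC4	PDZ and LIM domain protein 5	EVVKPVPITSPAVSK	N1	508	0.18	GlcNAc
scan=9003	P51610	Host cell factor 1	TIPMSAIITQAGATGVTSSPGIK	N1	1001	0.19	GlcNAc
scan=9004	P51610	Host cell factor 1	SPITIITTK	N1	664	0.20	GlcNAc
scan=9005	Q6UN15	Pre-mRNA 3'-end-processing factor FIP1	ETALPSTK	N1	362	0.20	GlcNAc
scan=9006	P02545	Prelamin-A/C	ASASGSGAQVGGPISSGSSASSVTVTR	N1	842	0.20	GlcNAc
scan=9007	P27816	Microtubule-associated protein 4	ASPSKPASAPASR	N1	309	0.24	GlcNAc
scan=9008	Q8NBJ4	Golgi membrane protein 1	LQAAGLPHTEVPQGK	H1N1S2	619	0.44	GalNAc
scan=9009	Q92753	Nuclear receptor ROR-beta	QQQSGEAEALAR	H1N1S2	273	0.68	GlcNAc
scan=9010	P14314	Glucosidase 2 subunit beta	SEALPTDLPAPSAPDLTEPK	H1N1S2	775	0.68	GalNAc
scan=9011	P30533	Alpha-2-macroglobulin receptor-associated protein	QVTSNSLSGTQEDGLDDPRLEK	N1	575	0.70	GalNAc
scan=9012	Q8IYS2	Uncharacterized protein KIAA2013	VAALQTVGPTAGPAPK	H1N1S2	695	0.73	GalNAc
scan=9013	Q8NBS9	Thioredoxin domain-containing protein 5	TETGATETVTPSEAPVLAAEPEADK	N1	609	0.77	GalNAc
scan=9014	P02786	Transferrin receptor protein 1	LAGTESPVREEPGEDFPAAR	H1N1S2	364	0.82	GalNAc
scan=9015	P02786	Transferrin receptor protein 1	LAGTESPVREEPGEDFPAAR	H1N1F1	406	0.85	GalNAc
scan=9016	Q10469	Alpha-1,6-mannosyl-glycoprotein 2-beta-N-acetylglucosaminyltransferase	GGDHPSVAVGIR	H1N1S2	456	0.90	GalNAc
scan=9017	P02786	Transferrin receptor protein 1	LAGTESPVREEPGEDFPAAR	H1N1S1	596	0.91	GalNAc
scan=9018	P26572	Alpha-1,3-mannosyl-glycoprotein 2-beta-N-acetylglucosaminyltransferase	GRVPTAAPPAQPR	H1N1S2	260	0.91	GalNAc
scan=9019	Q92520	Protein FAM3C	STKPPR	H1N1S2	285	0.97	GalNAc
scan=9020	O95994	Anterior gradient protein 2 homolog	DTTVKPGAK	N1	376	0.97	GalNAc
scan=9021	P14314	Glucosidase 2 subunit beta	SEALPTDLPAPSAPDLTEPK	N1	674	1.06	GalNAc
scan=9022	O60502	Protein O-GlcNAcase	QVAHSGAK	N1	374	1.13	GlcNAc
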