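gene	species	clade	1	2	3	4	5	6	7	8	9
Phvul.001G179300	Phaseolus_vulgaris	dicot	P	P	P	P	P	P	P	P	P
Phvul.007G147400	Phaseolus_vulgaris	dicot	P	P	P	P	P	P	P	P	P
Medtr7g102070	Medicago_truncatula	dicot	P	P	P	P	P	P	P	P	P
Medtr1g063170	Medicago_truncatula	dicot	P	P	P	P	P	P	P	P	P
Tp57577_TGAC_v2_gene32830	Trifolium_pratense	dicot	P	P	P	P	P	P	P	P	P
Glyma.19G184300	Glycine_max	dicot	P	P	P	P	P	P	P	P	P
Glyma.03G183600	Glycine_max	dicot	P	P	P	P	P	P	P	P	P
Glyma.10G055000	Glycine_max	dicot	P	P	P	P	P	P	P	P	P
Glyma.13G142100	Glycine_max	dicot	P	P	P	P	P	P	P	P	P
Prupe.7G129600	Prunus_persica	dicot	P	P	P	P	P	P	P	P	P
MDP0000231597	Malus_domestica	dicot	P	P	P	P	P	P	P	P	P
MDP0000183294	Malus_domestica	dicot	P	P	P	P	P	P	P	P	P
gene09601-v1.0-hybrid	Fragaria_vesca	dicot	P	P	P	P	P	P	P	P	P
Cucsa.306720	Cucumis_sativus	dicot	P	P	P	P	P	P	P	P	A
Ciclev10010916m.g	Citrus_clementina	dicot	P	P	P	P	P	P	P	P	P
orange1.1g000687m.g	Citrus_sinensis	dicot	P	P	P	P	P	P	P	P	P
Eucgr.K02930	Eucalyptus_grandis	dicot	P	P	P	P	P	P	P	P	P
Thecc1EG022244	Theobroma_cacao	dicot	P	P	P	P	P	P	P	P	P
Gorai.002G246800	Gossypium_raimondii	dicot	P	P	P	P	P	P	P	P	P
Gorai.006G163000	Gossypium_raimondii	dicot	P	P	P	P	P	P	P	P	P
Thhalv10016150m.g	Eutrema_salsugineum	dicot	P	P	P	P	P	P	P	A	P
Cagra.0558s0007	Capsella_grandiflora	dicot	P	P	P	P	P	P	P	P	P
Carubv10022511m.g	Capsella_rubella	dicot	P	P	P	P	P	P	P	P	P
Bostr.23794s0400	Boechera_stricta	dicot	P	P	P	P	P	P	P	P	P
Bra023087	Brassica_rapa_FPsc	dicot	P	P	P	P	P	P	P	P	P
Bra017216	Brassica_rapa_FPsc	dicot	P	P	P	P	P	P	P	P	P
Bo3g031410	Brassica_oleracea	dicot	P	P	P	P	P	P	P	P	P
Bo4g186480	Brassica_oleracea	dicot	P	P	P	P	P	P	P	P	P
Alyr_934330	Arabidopsis_lyrata	dicot	P	P	P	P	P	P	P	P	P
AT2G36910	Arabidopsis_thaliana	dicot	P	P	P	P	P	P	P	P	P
evm.TU.supercontig_102.36	Carica_papaya	dicot	P	P	P	P	P	P	P	ND	P
AUR62040338	Chenopodium_quinoa	dicot	P	P	P	P	P	P	P	P	P
AUR62042509	Chenopodium_quinoa	dicot	P	P	P	P	P	P	P	P	P
30078.t000079	Ricinus_communis	dicot	P	P	P	P	P	P	P	P	P
Manes.09G065700	Manihot_esculenta	dicot	P	P	P	P	P	P	P	P	P
Manes.08G011100	Manihot_esculenta	dicot	P	P	P	P	P	P	P	P	P
Lus10023929.g	Linum_usitatissimum	dicot	P	A	P	P	P	P	P	P	P
SapurV1A.1230s0070	Salix_purpurea	dicot	P	P	P	P	P	P	P	P	P
SapurV1A.0584s0030	Salix_purpurea	dicot	P	P	P	P	P	P	P	P	P
Potri.006G123900	Populus_trichocarpa	dicot	P	P	P	P	P	P	P	P	P
Potri.016G093600	Populus_trichocarpa	dicot	P	P	P	P	P	P	P	P	P
Solyc09g008240.2	Solanum_lycopersicum	dicot	P	P	P	P	P	P	P	P	P
PGSC0003DMG400003889	Solanum_tuberosum	dicot	P	P	P	P	P	P	P	P	P
Migut.J00652	Mimulus_guttatus	dicot	P	P	P	P	P	P	P	P	P
Migut.L01707	Mimulus_guttatus	dicot	P	P	P	P	P	P	A	P	P
Aquca_030_00072	Aquilegia_coerulea	dicot	P	P	P	P	P	P	P	P	P
Aquca_062_00022	Aquilegia_coerulea	dicot	P	P	P	P	P	P	P	P	P
Zosma16g00300	Zostera_marina	monocot	P	A	P	P	P	P	P	A	A
Spipo1G0026900	Spirodela_polyrhiza	monocot	P	P	P	P	P	P	P	P	P
LOC103714888	Phoenix_dactylifera	monocot	P	P	P	P	P	P	P	P	P
LOC103706998	Phoenix_dactylifera	monocot	P	P	P	P	P	P	P	P	P
GSMUA_Achr4G12130_001	Musa_acuminata	monocot	P	P	P	P	P	P	P	P	P
GSMUA_Achr4G04430_001	Musa_acuminata	monocot	P	P	P	P	P	P	P	P	P
Aco010196	Ananas_comosus	poales	P	P	P	P	P	P	P	P	P
Typha_ABCB1	Typha_latifolia	poales	P	P	P	P	P	P	P	P	P
Ecdeiocolea_ABCB1	Ecdeiocolea_sp	poales	A	P	P	P	P	P	P	P	P
Mayaca_ABCB1	Mayaca_sp	poales	P	P	P	A	P	P	P	P	A
Streptochaeta_ABCB1	Streptochaeta_sp	poaceae	A	P	P	P	P	P	P	P	P
Anomochloa_ABCB1	Anomochloa_sp	poaceae	A	P	P	A	ND	P	P	P	A
Pharus_ABCB1	Pharus_mezhii	poaceae	A	P	P	P	P	P	ND	P	ND
LPERR08G20590	Leersia_perrieri	poaceae	A	A	A	A	A	A	P	A	A
BGIOSGA029208	Oryza_sativa_indica	poaceae	A	A	A	A	P	A	P	A	A
LOC_Os08g45030	Oryza_sativa_japonica	poaceae	A	A	A	A	P	A	P	A	A
Aulonemia_ABCB1	Aulonemia_sp	poaceae	A	P	A	A	P	ND	P	A	ND
Bambusa_ABCB1	Bambusa_sp	poaceae	A	P	A	A	P	P	P	A	A
Phyllostachys_ABCB1	Phyllostachys_sp	poaceae	A	P	A	A	P	P	P	A	A
PH01000979	Phyllostachys_edulis	poaceae	A	P	A	A	P	P	P	A	A
PH01001487	Phyllostachys_edulis	poaceae	A	P	A	A	P	P	P	A	A
Bradi3g12627	Brachypodium_distachyon	poaceae	A	A	A	A	P	A	P	A	A
Brast03G311000	Brachypodium_stacei	poaceae	A	A	A	A	P	A	P	A	A
MLOC_5438	Hordeum_vulgare	poaceae	A	A	A	A	P	P	P	A	A
F775_52675	Aegilops_tauschii	poaceae	A	A	A	A	P	P	P	A	A
TRIUR3_22724	Triticum_urartu	poaceae	A	A	A	ND	P	P	P	A	A
JN672670	Eragrostis_tef	poaceae	A	A	A	A	A	P	P	A	A
JN672669	Eragrostis_tef	poaceae	A	A	A	A	A	P	P	A	A
Zoysia_ABCB1	Zoysia_sp	poaceae	A	A	A	A	A	A	P	A	A
Oropetium_20150105_14444	Oropetium_thomaeum	poaceae	A	P	A	A	A	A	P	A	A
Eleusine_ABCB1	Eleusine_coracana	poaceae	A	P	A	A	A	A	P	A	A
Micraira_ABCB1	Micraira_subulifolia	poaceae	A	A	A	A	P	P	ND	A	A
Phragmites_ABCB1	Phragmites_australis	poaceae	A	P	A	A	P	P	ND	A	A
Danthoniopsis_ABCB1	Danthoniopsis_dinteri	poaceae	A	P	A	A	P	ND	ND	A	A
Chasmanthium_ABCB1	Chasmanthium_laxum	poaceae	A	P	A	A	P	P	P	A	A
Paspalum_ABCB1	Paspalum_vaginatum	poaceae	A	P	A	A	A	P	P	A	A
GRMZM2G315375	Zea_mays	poaceae	A	P	A	A	P	P	P	A	A
AY372819.1	Sorghum_bicolor	poaceae	A	P	A	A	P	P	P	A	A
Arundinella_ABCB1	Arundinella_hirta	poaceae	A	P	A	A	P	ND	P	A	A
Andropogon_virginicus_ABCB1	Andropogon_virginicus	poaceae	A	P	A	A	P	P	P	A	A
Andropogon_gerardii_ABCB1	Andropogon_gerardii	poaceae	A	P	A	A	P	ND	P	A	A
Acroceras_ABCB1	Acroceras_macrum	poaceae	A	P	A	A	A	ND	P	A	ND
Sacciolepis_ABCB1	Sacciolepis_myosuroides	poaceae	A	P	A	A	P	ND	P	A	A
Dichanthelium_ABCB1	Dichanthelium_oligosanthes	poaceae	A	P	A	A	A	P	P	A	A
Pavir.6NG364900	Panicum_virgatum	poaceae	A	P	A	A	A	P	P	A	A
Pavir.6KG414900	Panicum_virgatum	poaceae	A	P	A	A	A	P	P	A	A
Pahal.F00317	Panicum_hallii	poaceae	A	P	A	A	A	P	P	A	A
Seita.6G253500	Setaria_italica	poaceae	A	A	A	A	A	P	P	A	A
Sevir.6G258000	Setaria_viridis	poaceae	A	A	A	A	A	P	P	A	A
CaABCB1	Cenchrus_americanus	poaceae	A	A	A	A	A	P	P	A	A
Brachiaria_ABCB1	Brachiaria_sp	poaceae	A	A	A	A	A	P	ND	A	ND
Urochloa_abyss_gt1kb	Urochloa_abyss	poaceae	A	A	A	A	A	P	P	A	A
AmTr_v1.0_scaffold00076.86	Amborella_trichopoda	basal	P	P	P	P	P	P	P	P	P
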