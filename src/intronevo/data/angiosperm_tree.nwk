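(AmTr_v1.0_scaffold00076.86,(((Aquca_030_00072,Aquca_062_00022),(((((((Phvul.001G179300,Phvul.007G147400),((Glyma.19G184300,Glyma.03G183600,Glyma.10G055000,Glyma.13G142100),((Medtr7g102070,Medtr1g063170),Tp57577_TGAC_v2_gene32830)))Fabaceae,((gene09601-v1.0-hybrid,(Prupe.7G129600,(MDP0000231597,MDP0000183294)))Rosaceae,Cucsa.306720)),((30078.t000079,(Manes.09G065700,Manes.08G011100)),(Lus10023929.g,((SapurV1A.1230s0070,SapurV1A.0584s0030),(Potri.006G123900,Potri.016G093600))))Malpighiales),(((((AT2G36910,Alyr_934330),((Cagra.0558s0007,Carubv10022511m.g),Bostr.23794s0400)),(Thhalv10016150m.g,((Bra023087,Bra017216),(Bo3g031410,Bo4g186480))))Brassicaceae,evm.TU.supercontig_102.36)Brassicales,((Thecc1EG022244,(Gorai.002G246800,Gorai.006G163000)),((Ciclev10010916m.g,orange1.1g000687m.g),Eucgr.K02930))))Rosids,((AUR62040338,AUR62042509),((Solyc09g008240.2,PGSC0003DMG400003889),(Migut.J00652,Migut.L01707))Asterids)))Eudicots,((Zosma16g00300,Spipo1G0026900)Alismatales,((LOC103714888,LOC103706998),((GSMUA_Achr4G12130_001,GSMUA_Achr4G04430_001),(Typha_ABCB1,(Aco010196,(Mayaca_ABCB1,(Ecdeiocolea_ABCB1,((Streptochaeta_ABCB1,Anomochloa_ABCB1)Anomochlooideae,(Pharus_ABCB1,(((LPERR08G20590,(BGIOSGA029208,LOC_Os08g45030))Oryzoideae,((Aulonemia_ABCB1,(Bambusa_ABCB1,(Phyllostachys_ABCB1,(PH01000979,PH01001487))))Bambusoideae,((Bradi3g12627,Brast03G311000),(MLOC_5438,(F775_52675,TRIUR3_22724)))Pooideae))BOP,((Chasmanthium_ABCB1,(Danthoniopsis_ABCB1,((Arundinella_ABCB1,((Andropogon_virginicus_ABCB1,Andropogon_gerardii_ABCB1),(GRMZM2G315375,AY372819.1)))Andropogoneae,(Paspalum_ABCB1,(Acroceras_ABCB1,(Sacciolepis_ABCB1,(Dichanthelium_ABCB1,(((Pavir.6NG364900,Pavir.6KG414900),Pahal.F00317)Panicinae,((Brachiaria_ABCB1,Urochloa_abyss_gt1kb)Melinidinae,((Seita.6G253500,Sevir.6G258000),CaABCB1)Cenchrinae)))))Paniceae))))Panicoideae,(Phragmites_ABCB1,(Micraira_ABCB1,((JN672670,JN672669),(Zoysia_ABCB1,(Oropetium_20150105_14444,Eleusine_ABCB1)))Chloridoideae)))PACMAD)))Poaceae)Graminid)))Poales))))Monocots))Angiosperms;
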