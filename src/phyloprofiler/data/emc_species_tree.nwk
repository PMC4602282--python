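(((Homo_sapiens:1.0,(Saccharomyces_cerevisiae:1.0,(Piromyces_sp.:1.0,(Nosema_ceranae:1.0,Encephalitozoon_cuniculi:1.0)Microsporidia:1.0)Chytrid_clade:1.0)Fungi:1.0)Opisthokonta:1.0,(Dictyostelium_discoideum:1.0,Entamoeba_histolytica:1.0)Amoebozoa:1.0)Amorphea:1.0,((Naegleria_gruberi:1.0,(Giardia_intestinalis:1.0,Trichomonas_vaginalis:1.0)Metamonada:1.0)Excavata:1.0,(((Blastocystis_hominis:1.0,Phytophthora_sojae:1.0)Stramenopiles:1.0,(Theileria_parva:1.0,Cryptosporidium_parvum:1.0)Apicomplexa:1.0)SAR:1.0,((Arabidopsis_thaliana:1.0,Cyanidioschyzon_merolae:1.0)Archaeplastida:1.0,Emiliania_huxleyi:1.0)Plastid_clade:1.0)Diaphoretickes:1.0)N_Excavata_Diaphoretickes:1.0)LECA;
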