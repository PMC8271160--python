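species_id	life_form
Amborella_trichopoda	tree
Carica_papaya	tree
Citrus_clementina	tree
Coffea_canephora	tree
Eucalyptus_grandis	tree
Hevea_brasiliensis	tree
Malus_domestica	tree
Populus_trichocarpa	tree
Prunus_persica	tree
Pyrus_bretschneideri	tree
Theobroma_cacao	tree
Ziziphus_jujuba	tree
Cycas_micholitzii	tree
Ginkgo_biloba	tree
Gnetum_montanum	tree
Picea_abies	tree
Picea_glauca	tree
Picea_sitchensis	tree
Pinus_pinaster	tree
Pinus_sylvestris	tree
Pinus_taeda	tree
Pseudotsuga_menziesii	tree
Taxus_baccata	tree
Arabidopsis_lyrata	perennial_herb
Brassica_oleracea	perennial_herb
Cajanus_cajan	perennial_herb
Capsicum_annuum	perennial_herb
Erythranthe_guttata	perennial_herb
Fragaria_vesca	perennial_herb
Marchantia_polymorpha	perennial_herb
Nelumbo_nucifera	perennial_herb
Oryza_sativa	perennial_herb
Ricinus_communis	perennial_herb
Selaginella_moellendorffii	perennial_herb
Solanum_lycopersicum	perennial_herb
Solanum_tuberosum	perennial_herb
Trifolium_pratense	perennial_herb
Utricularia_gibba	perennial_herb
Amaranthus_hypochondriacus	annual_herb
Arabidopsis_thaliana	annual_herb
Arachis_ipaensis	annual_herb
Beta_vulgaris	annual_herb
Brassica_rapa	annual_herb
Capsella_rubella	annual_herb
Chenopodium_quinoa	annual_herb
Cicer_arietinum	annual_herb
Citrullus_lanatus	annual_herb
Corchorus_olitorius	annual_herb
Cucumis_melo	annual_herb
Cucumis_sativus	annual_herb
Daucus_carota	annual_herb
Glycine_max	annual_herb
Medicago_truncatula	annual_herb
Petunia_axillaris	annual_herb
Physcomitrella_patens	annual_herb
Schrenkiella_parvula	annual_herb
Tarenaya_hassleriana	annual_herb
Vigna_radiata	annual_herb
Zea_mays	annual_herb
Chlamydomonas_reinhardtii	alga
Micromonas_commoda	alga
Actinidia_chinensis	shrub
Gossypium_raimondii	shrub
Manihot_esculenta	shrub
Vitis_vinifera	shrub
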