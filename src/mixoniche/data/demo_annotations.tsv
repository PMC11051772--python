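taxon	rank	mode	source
Karlodinium veneficum	species	M	literature
Chrysophyceae_Clade_G_sp.	species	M	literature
Haptophyta_HAP2_XXX_sp.	species	M	literature
Geminigera cryophila	species	M	literature
Triparma mediterranean	species	M	literature
Cryptomonadales_XX_sp.	species	M	literature
Chrysochromulina	genus	M	literature
Florenciella	genus	M	literature
Prymnesiophyceae_XXX	genus	M	literature
Dictyochales_X	genus	M	literature
Florenciellales_X	genus	M	literature
Chrysophyceae_Clade-H_X	genus	M	literature
Micromonas	genus	A	literature
MOCH.2_XXX_sp.	species	A	literature
Chlorophyta_XXXX_sp.	species	A	literature
Bacillariophyta_XXX_sp.	species	A	literature
MAST.4C_XX_sp.	species	H	literature
Telonemia_Group2_X_sp.	species	H	literature
Telonemia_Group1	genus	H	literature
NPK2_lineage_X_sp.	species	H	literature
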