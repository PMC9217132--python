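lh_bankssts
lh_caudalanteriorcingulate
lh_caudalmiddlefrontal
lh_cuneus
lh_entorhinal
lh_frontalpole
lh_fusiform
lh_inferiorparietal
lh_inferiortemporal
lh_insula
lh_isthmuscingulate
lh_lateraloccipital
lh_lateralorbitofrontal
lh_lingual
lh_medialorbitofrontal
lh_middletemporal
lh_paracentral
lh_parahippocampal
lh_parsopercularis
lh_parsorbitalis
lh_parstriangularis
lh_pericalcarine
lh_postcentral
lh_posteriorcingulate
lh_precentral
lh_precuneus
lh_rostralanteriorcingulate
lh_rostralmiddlefrontal
lh_superiorfrontal
lh_superiorparietal
lh_superiortemporal
lh_supramarginal
lh_temporalpole
lh_transversetemporal
rh_bankssts
rh_caudalanteriorcingulate
rh_caudalmiddlefrontal
rh_cuneus
rh_entorhinal
rh_frontalpole
rh_fusiform
rh_inferiorparietal
rh_inferiortemporal
rh_insula
rh_isthmuscingulate
rh_lateraloccipital
rh_lateralorbitofrontal
rh_lingual
rh_medialorbitofrontal
rh_middletemporal
rh_paracentral
rh_parahippocampal
rh_parsopercularis
rh_parsorbitalis
rh_parstriangularis
rh_pericalcarine
rh_postcentral
rh_posteriorcingulate
rh_precentral
rh_precuneus
rh_rostralanteriorcingulate
rh_rostralmiddlefrontal
rh_superiorfrontal
rh_superiorparietal
rh_superiortemporal
rh_supramarginal
rh_temporalpole
rh_transversetemporal
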