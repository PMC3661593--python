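site_id,landscape_context,round,plot_id,spatial_config,plant_species,insect_morphotype,visit_count
ALL,pooled,1,ALL,systematic,community,solitary bees,5038
ALL,pooled,1,ALL,systematic,community,Apis mellifera,36
ALL,pooled,1,ALL,systematic,community,bumblebees,5567
ALL,pooled,1,ALL,systematic,community,Coleoptera,565
ALL,pooled,1,ALL,systematic,community,Lepidoptera,118
ALL,pooled,1,ALL,systematic,community,Syrphidae,4789
ALL,pooled,1,ALL,systematic,community,other flies,1686
ALL,pooled,1,ALL,systematic,community,bugs,32
ALL,pooled,1,ALL,systematic,community,other Hymenoptera,26
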