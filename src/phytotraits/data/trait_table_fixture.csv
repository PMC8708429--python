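taxon_id,taxon_name,rank,parent_genus,group,n_fixation,mixotrophy,motility,buoyancy,harmful,excluded_category,override_note
DOLI_FLO,Dolichospermum flosaquae,species,Dolichospermum,cyanobacteria,1,0,0,1,1,,
ANABAENA,Anabaena,genus,,cyanobacteria,1,0,0,1,1,,harmful
APHA_FLO,Aphanizomenon flosaquae,species,Aphanizomenon,cyanobacteria,1,0,0,1,1,,
APHANIZOMENON,Aphanizomenon,genus,,cyanobacteria,1,0,0,1,1,,harmful
SNOW_LAC,Snowella lacustris,species,Snowella,cyanobacteria,0,0,0,1,0,,
SNOWELLA,Snowella,genus,,cyanobacteria,0,0,0,0,0,,buoyancy
AMPH_CRA,Amphidinium crassum,species,Amphidinium,eukaryote,0,1,1,0,1,,
AMPHIDINIUM,Amphidinium,genus,,eukaryote,0,1,1,0,0,,harmful
PRYMNESIALES,Prymnesiales,order,,eukaryote,0,1,1,0,1,,harmful
CHRYSOCHROMULINA,Chrysochromulina,genus,,eukaryote,0,1,1,0,1,,harmful
SKEL_MAR,Skeletonema marinoi,species,Skeletonema,eukaryote,0,0,0,0,0,,
EBRI_TRI,Ebria tripartita,species,Ebria,eukaryote,0,0,1,0,0,heterotroph,
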