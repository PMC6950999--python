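group,gene,cgi_chrom,cgi_start,cgi_end,state,n_dmp,deg
HOX proteins,HOXD4,chr2,177014948,177015214,hyper,2,
HOX proteins,HOXD3,chr2,177029413,177029941,hyper,1,up
HOX proteins,MEIS1,chr2,66672431,66673636,hypo,3,
HOX proteins,HOXA3,chr7,27163819,27164098,hyper,3,up
HOX proteins,HOXB3,chr17,46631800,46632212,hyper,1,up
HIST1 proteins,HIST1H3A,chr6,26020671,26021125,hyper,1,
HIST1 proteins,HIST1H4A,chr6,26020671,26021125,hyper,3,
HIST1 proteins,HIST1H2BK,chr6,27107138,27107394,hyper,1,
HIST1 proteins,HIST1H2AL,chr6,27833120,27833406,hyper,4,
HIST1 proteins,HIST1H1B,chr6,27835190,27835461,hyper,1,
ZNF transcription factors,PRDM16,chr1,3102540,3103352,hypo,2,
ZNF transcription factors,ZNF512,chr2,27805754,27806078,hyper,1,down
ZNF transcription factors,ZNF518B,chr4,10458129,10459353,hyper,1,down
ZNF transcription factors,CXXC5,chr5,139040819,139041028,hypo,1,up
ZNF transcription factors,FEZF1,chr7,121943867,121944538,hypo,3,
ZNF transcription factors,TRPS1,chr8,116660432,116660747,hyper,1,
ZNF transcription factors,ZNF263,chr16,3332472,3333847,hypo,1,
ZNF transcription factors,ZNF397OS,chr18,32847284,32848130,hyper,1,
ZNF transcription factors,ZNF441,chr19,11877720,11878280,hypo,1,up
ZNF transcription factors,ZNF69,chr19,11998804,11999131,hypo,10,up
ZNF transcription factors,ZNF700,chr19,12035899,12036433,hypo,9,up
ZNF transcription factors,ZNF763,chr19,12076029,12076366,hypo,9,
ZNF transcription factors,ZNF529,chr19,37095680,37096589,hyper,1,
Transcription factors,SP5,chr2,171569877,171573904,hypo,2,
Transcription factors,SP3,chr2,174828330,174830617,hypo,1,
Transcription factors,NEUROD6,chr7,31375845,31376542,hyper,1,
Transcription factors,PAX5,chr9,36985986,36986924,hypo,1,up
Transcription factors,CREBZF,chr11,85374872,85376234,hypo,1,
Transcription factors,SIM2,chr21,38079941,38081833,hypo,1,
DNA-binding proteins,COLEC11,chr2,3683029,3683290,hypo,1,
DNA-binding proteins,WRNIP1,chr6,2765203,2766775,hyper,2,
DNA-binding proteins,JRK,chr8,143750759,143751448,hypo,2,
DNA-binding proteins,FBXO21,chr12,117627650,117628488,hypo,2,up
DNA-binding proteins,KDM2B,chr12,121975028,121976140,hyper,1,
DNA-binding proteins,POLE,chr12,133249979,133250243,hypo,1,down
DNA-binding proteins,WNT1,chr12,49371690,49375550,hyper,2,
DNA-binding proteins,SMC1B,chr22,45809191,45809953,hypo,2,
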