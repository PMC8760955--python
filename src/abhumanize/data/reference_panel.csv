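therapeutic,vh_gene,vh_overlap_pct,vh_adjusted_overlap_pct,vh_n_tool,vh_n_exp,vh_mutation_ratio_pct,vl_gene,vl_overlap_pct,vl_adjusted_overlap_pct,vl_n_tool,vl_n_exp,vl_mutation_ratio_pct
AntiCD28,V3,63,79,19,33,58,KV4,64,73,11,19,58
Campath,V4,75,88,16,39,41,KV1,67,67,3,14,21
Bevacizumab,V3,50,57,14,25,56,KV1,89,100,9,16,56
Herceptin,V3,59,78,27,32,84,KV1,88,88,8,22,36
Omalizumab,V3,62,76,21,34,62,KV1,89,95,19,25,76
Eculizumab,V1,73,73,15,23,65,KV1,83,83,12,20,60
Tocilizumab,V4,64,86,14,23,61,KV1,78,89,9,19,47
Pembrolizumab,V1,73,73,11,23,48,KV3,75,75,12,20,60
Pertuzumab,V3,68,79,19,32,59,KV1,80,90,10,20,50
Ixekizumab,V1,75,75,12,29,41,KV2,78,100,9,12,75
Palivizumab,V2,75,83,12,18,67,KV1,77,92,13,26,50
Certolizumab,V3,61,78,18,31,58,KV1,80,90,10,20,50
Idarucizumab,V4,80,80,15,24,63,KV2,67,67,6,8,75
Reslizumab,V3,50,80,10,21,48,KV1,83,100,6,20,30
Solanezumab,V3,50,70,10,16,63,KV2,88,100,8,10,80
Lorvotuzumab,V3,90,90,10,13,77,KV2,82,82,11,13,85
Pinatuzumab,V3,61,78,23,33,70,KV1,74,79,19,23,83
Etaracizumab,V3,58,83,12,16,75,KV3,62,69,13,25,52
Talacotuzumab,V5,78,83,18,33,55,KV4,73,73,11,16,69
Rovalpituzumab,V1,67,67,21,30,70,KV3,64,79,14,26,54
Clazakizumab,V3,86,86,7,27,26,KV1,75,75,4,22,18
Ligelizumab,V1,64,64,11,21,52,KV3,64,91,11,21,52
Crizanlizumab,V1,64,64,11,23,48,KV1,85,95,20,23,87
Mogamulizumab,V3,67,67,6,15,40,KV2,67,67,6,12,50
Refanezumab,V7,87,87,15,17,88,KV4,92,100,12,17,71
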