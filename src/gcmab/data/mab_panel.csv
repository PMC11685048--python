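clonotype_id,vh_gene,vk_gene,mab_id,vh_cdr,vh_fw,vk_cdr,vk_fw,elisa_threshold,ova_asinh
c179,IGHV1-42*01,IGKV4-80*01,germline,0,0,0,0,>1000,NA
c179,IGHV1-42*01,IGKV4-80*01,p7.BC76,1,0,1,0,19.03,2.14
c179,IGHV1-42*01,IGKV4-80*01,p7.BC41,0,1,2,1,>1000,0.06
c179,IGHV1-42*01,IGKV4-80*01,p7.BC49,0,1,0,0,0.27,1.86
c179,IGHV1-42*01,IGKV4-80*01,p8.BC75,1,0,1,0,4.85,1.53
c179,IGHV1-42*01,IGKV4-80*01,p8.BC46,0,0,0,0,3.86,1.46
c248,IGHV1-26*01,IGKV4-61*01,germline,0,0,0,0,>1000,NA
c248,IGHV1-26*01,IGKV4-61*01,p9.BC45,2,3,0,0,>1000,0.03
c248,IGHV1-26*01,IGKV4-61*01,p9.BC76,2,1,0,0,14.94,0.04
c248,IGHV1-26*01,IGKV4-61*01,p9.BC37,2,1,0,0,615.18,0.44
c248,IGHV1-26*01,IGKV4-61*01,p9.BC61,0,1,0,0,539,0.21
c248,IGHV1-26*01,IGKV4-61*01,p9.BC64,0,0,0,0,412,0.60
c127,IGHV1-64*01,IGKV1-99*01,germline,0,0,0,0,0.75,NA
c127,IGHV1-64*01,IGKV1-99*01,p9.BC16,1,1,0,2,219,1.35
c127,IGHV1-64*01,IGKV1-99*01,p9.BC78,1,0,0,0,502,0.27
c127,IGHV1-64*01,IGKV1-99*01,p9.BC41,1,1,0,1,1.74,1.89
c127,IGHV1-64*01,IGKV1-99*01,p10.BC3,0,0,0,0,1.6,1.57
c127,IGHV1-64*01,IGKV1-99*01,p9.BC1,1,0,0,0,129,0.68
c127,IGHV1-64*01,IGKV1-99*01,p9.BC18,0,0,0,0,3.2,1.27
c127,IGHV1-64*01,IGKV1-99*01,p10.BC50,1,1,0,0,8.9,2.06
c87,IGHV1-63*01,IGKV1-117*01,germline,0,0,0,0,>1000,NA
c87,IGHV1-63*01,IGKV1-117*01,p8.BC50,2,5,2,3,0.8,1.93
c87,IGHV1-63*01,IGKV1-117*01,p7.BC31,2,1,0,1,336,0.48
c87,IGHV1-63*01,IGKV1-117*01,p7.BC19,1,2,0,2,10.8,0.24
c87,IGHV1-63*01,IGKV1-117*01,p7.BC16,1,3,1,0,1.94,1.43
c87,IGHV1-63*01,IGKV1-117*01,p8.BC83,2,1,1,1,1.73,1.41
c87,IGHV1-63*01,IGKV1-117*01,p7.BC1,0,0,1,0,0.74,1.64
c87,IGHV1-63*01,IGKV1-117*01,p7.BC27,0,0,0,0,0.42,1.09
c184,IGHV1-81*01,IGKV13-84*01,germline,0,0,0,0,>1000,NA
c184,IGHV1-81*01,IGKV13-84*01,p10.BC30,1,1,0,4,14.6,0.13
c184,IGHV1-81*01,IGKV13-84*01,p9.BC6,2,0,2,2,>1000,0.03
c184,IGHV1-81*01,IGKV13-84*01,p10.BC57,0,0,0,0,352,1.47
c184,IGHV1-81*01,IGKV13-84*01,p9.BC75,1,1,0,0,451,0.05
c184,IGHV1-81*01,IGKV13-84*01,p10.BC74,1,0,0,4,24.8,0.33
c184,IGHV1-81*01,IGKV13-84*01,p10.BC38,1,1,0,0,280,0.94
c184,IGHV1-81*01,IGKV13-84*01,p9.BC25,1,2,0,0,>1000,0.00
c184,IGHV1-81*01,IGKV13-84*01,p9.BC40,2,0,0,0,17,0.31
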