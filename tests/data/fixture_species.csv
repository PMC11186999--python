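species,clade,head_shape,head_length_um,head_width_um,method,nucleus_fraction,haploid_n,L_max_um,L_min_um,genome_pg,source
msp0001,mammal,spatulate,4.9053,3.1626,optical,0.576,20,2.6987,0.3646,,synthetic
msp0002,mammal,spatulate,3.0125,1.6958,optical,0.703,18,1.4742,0.3169,2.803,synthetic
msp0003,mammal,spatulate,5.6539,2.8941,optical,,19,0.6494,0.6185,3.4014,synthetic
msp0004,mammal,spatulate,4.0655,2.2848,TEM,,25,1.5737,0.2552,2.2311,synthetic
msp0005,mammal,spatulate,5.91,4.0469,optical,,24,2.4103,0.5281,3.1367,synthetic
msp0006,mammal,spatulate,2.9903,2.1607,SEM,0.644,14,2.8456,2.7101,,synthetic
msp0007,mammal,spatulate,4.1877,2.0778,SEM,0.888,26,1.7711,0.6183,3.4439,synthetic
msp0008,mammal,spatulate,2.8047,1.5115,SEM,,15,3.2771,1.3044,1.9106,synthetic
msp0009,mammal,spatulate,5.0565,3.1566,optical,0.708,12,7.2266,0.9411,3.8428,synthetic
msp0010,mammal,spatulate,6.4203,2.7643,TEM,,22,6.7477,1.5077,4.7829,synthetic
msp0011,mammal,spatulate,2.8531,1.5165,SEM,0.56,26,2.84,0.5738,3.6615,synthetic
msp0012,mammal,spatulate,2.4318,1.1021,SEM,,21,4.8423,1.0101,2.8034,synthetic
ssp0001,sauropsid,vermiform,5.4634,,optical,,17,4.1823,0.2656,,synthetic
ssp0002,sauropsid,vermiform,9.1661,,optical,,14,4.6834,0.1572,1.379,synthetic
ssp0003,sauropsid,vermiform,5.9574,,optical,0.863,21,3.2554,0.09,,synthetic
ssp0004,sauropsid,vermiform,10.8221,,TEM,0.859,15,6.0228,0.2349,1.3456,synthetic
ssp0005,sauropsid,vermiform,6.3553,,optical,0.898,13,5.4933,0.2017,1.307,synthetic
ssp0006,sauropsid,vermiform,5.1851,,SEM,,17,5.4071,0.3208,1.3544,synthetic
ssp0007,sauropsid,vermiform,5.0326,,optical,,17,6.6987,0.438,1.9296,synthetic
ssp0008,sauropsid,vermiform,1.3293,,TEM,,11,8.5663,1.3526,1.2256,synthetic
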