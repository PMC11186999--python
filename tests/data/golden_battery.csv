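cohort,response,predictor,estimator,N,lambda_hat,intercept,slope,SE_slope,t,p,R2,significant,power_law_constant
spatulate_mammal,log10_n,log10_area,PGLS,12,0,1.18412,0.106256,0.162696,0.653094,0.528425,0.0409083,0,15.28
spatulate_mammal,log10_n,log10_C,PGLS,10,0,1.25149,0.111253,0.335487,0.331615,0.7487,0.0135597,0,17.8438
spatulate_mammal,log10_n,log10_area_per_pg,PGLS,10,0,1.25799,0.0921404,0.188887,0.487808,0.638773,0.0288854,0,18.1132
spatulate_mammal,log10_K,log10_area,PGLS,12,0,0.552076,0.014088,0.437862,0.0321745,0.974966,0.000103509,0,3.56514
spatulate_mammal,log10_K,log10_C,PGLS,10,0,0.502014,0.180264,0.741276,0.24318,0.813985,0.00733784,0,3.17698
spatulate_mammal,log10_K,log10_area_per_pg,PGLS,10,0,0.655727,-0.124339,0.419892,-0.296122,0.774678,0.0108422,0,4.52613
vermiform_sauropsid,log10_n,log10_length,PGLS,8,0,1.07601,0.142179,0.160906,0.883618,0.410906,0.115146,0,11.9126
vermiform_sauropsid,log10_n,log10_C,PGLS,6,0,1.05265,0.699232,0.389694,1.79431,0.14721,0.445949,0,11.2889
vermiform_sauropsid,log10_n,log10_length_per_pg,PGLS,6,0,1.0977,0.0925076,0.139024,0.665405,0.542197,0.0996596,0,12.5227
vermiform_sauropsid,log10_K,log10_length,PGLS,8,0,0.547075,0.951549,0.273499,3.47917,0.0131558,0.668593,1,3.52432
vermiform_sauropsid,log10_K,log10_C,PGLS,6,1,1.10837,1.35734,1.09243,1.2425,0.281917,0.278473,0,12.8343
vermiform_sauropsid,log10_K,log10_length_per_pg,PGLS,6,0,0.691125,0.888713,0.241253,3.68373,0.0211346,0.772338,1,4.91049
pooled,log10_n,log10_C,PGLS,16,0,1.11214,0.37982,0.128887,2.94693,0.0106102,0.382836,1,12.9463
pooled,log10_n,s,PGLS,20,0,1.29243,-0.106043,0.0464712,-2.28191,0.0348808,0.224375,1,19.608
pooled,log10_K,log10_C,PGLS,16,0.664817,1.16723,-0.743686,0.585353,-1.27049,0.224618,0.103377,0,14.6969
pooled,log10_K,s,PGLS,20,0.138368,0.563346,0.722425,0.161983,4.45988,0.000302646,0.524947,1,3.65886
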