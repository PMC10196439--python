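tissue,f_ew,f_iw,f_nl,f_npl,ap_mg_per_g
adipose,0.135,0.017,0.790,0.0016,0.40
bone,0.100,0.346,0.017,0.0017,0.67
brain,0.162,0.620,0.039,0.0015,0.40
gut,0.282,0.475,0.038,0.0125,2.41
heart,0.320,0.456,0.014,0.0111,2.25
kidney,0.273,0.483,0.012,0.0242,5.03
liver,0.161,0.573,0.014,0.0240,4.56
lung,0.336,0.446,0.022,0.0128,3.91
muscle,0.118,0.630,0.010,0.0072,1.53
pancreas,0.120,0.664,0.041,0.0093,1.67
skin,0.382,0.291,0.060,0.0044,1.32
spleen,0.207,0.579,0.0077,0.0113,3.18
reproductive,0.323,0.522,0.0060,0.0120,2.00
rest,0.300,0.450,0.0500,0.0070,1.50
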