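label,name,chi_mean,a_tissue,b_tissue,is_brain_tissue,is_piecewise_constant
1,caudate,0.044,-0.012,1.118,1,0
2,globus_pallidus,0.131,-0.026,0.843,1,0
3,putamen,0.038,-0.025,1.852,1,0
4,red_nucleus,0.100,-0.044,1.780,1,0
5,dentate_nucleus,0.152,-0.064,1.708,1,0
6,substantia_nigra,0.111,-0.075,1.491,1,0
7,thalamus,0.020,-0.086,1.275,1,0
8,white_matter,-0.030,-0.078,1.147,1,0
9,gray_matter,0.020,-0.095,1.402,1,0
10,csf,0.019,-0.006,0.067,0,0
11,blood,0.190,-0.058,0.047,0,0
12,fat,0.019,0.000,0.000,0,1
13,bone,-2.100,0.000,0.000,0,1
14,air,9.200,0.000,0.000,0,1
15,muscle,0.000,0.000,0.000,0,1
16,calcification,-3.300,-0.012,0.000,0,0
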