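label,name,chi_mean,a_tissue,b_tissue,is_brain_tissue,is_piecewise_constant
1,caudate,0.044,-0.011,1.230,1,0
2,globus_pallidus,0.121,-0.023,0.927,1,0
3,putamen,0.043,-0.022,2.038,1,0
4,red_nucleus,0.090,-0.040,1.958,1,0
5,dentate_nucleus,0.162,-0.058,1.879,1,0
6,substantia_nigra,0.121,-0.068,1.640,1,0
7,thalamus,0.025,-0.078,1.402,1,0
8,white_matter,0.005,-0.070,1.262,1,0
9,gray_matter,0.020,-0.085,1.543,1,0
10,csf,0.019,-0.006,0.073,0,0
11,blood,0.170,-0.052,0.052,0,0
12,fat,0.019,0.000,0.000,0,1
13,bone,-2.100,0.000,0.000,0,1
14,air,9.200,0.000,0.000,0,1
15,muscle,0.000,0.000,0.000,0,1
16,calcification,0.019,-0.011,0.000,0,0
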