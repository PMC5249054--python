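# Reference cohort: per-sample micro-CT morphometry summaries of 29 vacuum-assisted
# breast-biopsy specimens (9 um isotropic voxels). Columns: histopathology B-class,
# mammographic BIRADS category, histologic group (A benign, B uncertain, C malignant),
# patient age [y], number of detected microcalcifications, mean object volume
# [1e5 um^3, printed precision], morphology flags (1 present / 0 absent), and the
# mean and SD of the structure model index over the sample's objects.
sample_id,b_class,birads,group,age,n_objects,mean_V_1e5_um3,fl,fp,ch,ns,smi_mean,smi_sd
1,B2,4,A,52,23,16,0,1,0,0,3.27,0.33
2,B1,4,A,58,1,1,1,0,0,0,3.02,0
3,B2,4,A,58,13,65,0,1,0,0,2.95,0.39
4,B2,4,A,63,5,6,0,1,0,0,2.79,0.45
5,B2,4,A,57,11,30,0,0,0,1,3.14,0.18
6,B2,4,A,65,53,28,0,0,0,1,3.30,0.28
7,B2,4,A,57,18,325,0,0,0,1,2.76,0.35
8,B2,4,A,52,121,43,0,0,0,1,3.29,0.29
9,B1,2,A,60,10,82,0,0,0,1,3.07,0.12
10,B2,4,A,53,5,25,0,1,0,0,2.19,0.80
11,B2,4,A,74,31,13,0,0,0,1,3.30,0.18
12,B2,4,A,59,2,2,0,0,0,1,2.86,0.04
13,B2,4,A,54,6,737,0,0,0,1,2.89,0.24
14,B2,4,A,54,4,7,0,1,0,0,2.89,0.45
15,B4,4,B,60,5,473,0,0,1,0,2.59,0.60
16,B3,4,B,65,36,40,0,1,0,0,2.52,0.45
17,B3,4,B,54,7,9,0,0,0,1,3.14,0.09
18,B3,4,B,52,150,22,0,0,0,1,3.15,0.24
19,B3,4,B,52,15,37,0,1,0,0,2.75,0.46
20,B3,4,B,86,67,22,1,0,0,0,3.07,0.24
21,B3,4,B,52,10,16,0,0,0,1,3.10,0.20
22,B5,5,C,76,58,36,1,0,0,0,2.95,0.25
23,B5,4,C,52,25,14,1,0,0,0,3.00,0.27
24,B5,5,C,49,30,15,0,1,0,0,2.87,0.54
25,B5,4,C,60,31,19,1,0,0,0,3.03,0.20
26,B5,4,C,69,1,3,0,0,0,1,2.79,0
27,B5,4,C,63,30,87,0,1,0,0,3.11,0.31
28,B5,4,C,70,19,152,0,1,0,0,3.15,0.30
29,B5,3,C,74,42,70,1,1,0,0,3.08,0.30
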