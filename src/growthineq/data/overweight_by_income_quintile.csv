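cohort,visit,q1,q2,q3,q4,q5,sii,sii_lo,sii_hi,rii,rii_lo,rii_hi,provenance
1982,1y,5.0,7.9,4.4,7.8,9.2,3.93,-0.69,8.55,1.85,0.9,3.8,"published overweight-by-quintile table, 1982 cohort, 1y row"
1993,1y,12.9,9.9,8.0,14.4,9.1,-0.14,-5.66,5.38,0.98,0.52,1.87,"published overweight-by-quintile table, 1993 cohort, 1y row"
2004,1y,9.2,8.1,9.5,9.5,8.4,-0.12,-3.29,3.05,0.99,0.67,1.46,"published overweight-by-quintile table, 2004 cohort, 1y row"
1982,2y,7.2,6.2,8.5,9.9,10.5,5.05,2.31,7.8,1.93,1.35,2.76,"published overweight-by-quintile table, 1982 cohort, 2y row"
2004,2y,7.5,8.2,7.0,8.9,10.0,2.86,-0.22,5.94,1.46,0.97,2.18,"published overweight-by-quintile table, 2004 cohort, 2y row"
1982,4y,5.3,6.4,5.4,9.8,10.8,7.18,4.52,9.84,2.84,1.92,4.2,"published overweight-by-quintile table, 1982 cohort, 4y row"
1993,4y,6.0,10.1,8.7,13.5,16.0,12.69,6.83,18.54,4.36,2.18,8.73,"published overweight-by-quintile table, 1993 cohort, 4y row"
2004,4y,8.7,10.3,12.6,14.9,15.2,8.8,5.09,12.51,2.27,1.61,3.22,"published overweight-by-quintile table, 2004 cohort, 4y row"
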