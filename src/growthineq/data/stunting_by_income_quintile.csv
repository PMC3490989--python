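cohort,visit,q1,q2,q3,q4,q5,sii,sii_lo,sii_hi,rii,rii_lo,rii_hi,provenance
1982,1y,19.8,10.6,6.0,5.5,3.6,-16.8,-21.8,-11.82,0.1,0.04,0.21,"published stunting-by-quintile table, 1982 cohort, 1y row"
1993,1y,16.8,11.5,6.9,5.4,4.8,-18.52,-24.84,-12.19,0.19,0.11,0.34,"published stunting-by-quintile table, 1993 cohort, 1y row"
2004,1y,8.1,9.1,5.7,3.8,3.1,-7.6,-10.23,-4.98,0.25,0.15,0.4,"published stunting-by-quintile table, 2004 cohort, 1y row"
1982,2y,28.9,21.8,10.1,7.1,3.6,-32.04,-35.34,-28.74,0.05,0.04,0.07,"published stunting-by-quintile table, 1982 cohort, 2y row"
2004,2y,8.8,8.4,3.8,2.4,1.5,-10.34,-12.74,-7.93,0.09,0.05,0.17,"published stunting-by-quintile table, 2004 cohort, 2y row"
1982,4y,26.0,16.0,6.3,5.3,2.7,-27.79,-30.83,-24.75,0.04,0.03,0.06,"published stunting-by-quintile table, 1982 cohort, 4y row"
1993,4y,11.8,4.6,5.5,2.3,2.6,-14.24,-19.34,-9.15,0.11,0.05,0.25,"published stunting-by-quintile table, 1993 cohort, 4y row"
2004,4y,6.7,5.3,3.1,2.0,1.1,-7.21,-9.3,-5.11,0.11,0.06,0.21,"published stunting-by-quintile table, 2004 cohort, 4y row"
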