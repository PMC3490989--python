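visit,indicator,cohort,prevalence_pct,cases,visit_n,p_value,provenance
birth,underweight,1982,7.1,418,5914,0.118,"published prevalence-by-cohort table, birth underweight row, 1982 cohort"
birth,underweight,1993,7.8,405,5249,0.118,"published prevalence-by-cohort table, birth underweight row, 1993 cohort"
birth,underweight,2004,7.9,332,4231,0.118,"published prevalence-by-cohort table, birth underweight row, 2004 cohort"
birth,stunting,1993,9.3,476,5249,<0.001,"published prevalence-by-cohort table, birth stunting row, 1993 cohort"
birth,stunting,2004,12.4,513,4231,<0.001,"published prevalence-by-cohort table, birth stunting row, 2004 cohort"
birth,wasting,1993,3.6,179,5249,<0.001,"published prevalence-by-cohort table, birth wasting row, 1993 cohort"
birth,wasting,2004,1.3,50,4231,<0.001,"published prevalence-by-cohort table, birth wasting row, 2004 cohort"
birth,overweight,1993,2.2,112,5249,0.261,"published prevalence-by-cohort table, birth overweight row, 1993 cohort"
birth,overweight,2004,2.5,105,4231,0.261,"published prevalence-by-cohort table, birth overweight row, 2004 cohort"
1y,underweight,1982,4.0,58,1457,0.001,"published prevalence-by-cohort table, 1y underweight row, 1982 cohort"
1y,underweight,1993,2.6,65,1361,0.001,"published prevalence-by-cohort table, 1y underweight row, 1993 cohort"
1y,underweight,2004,2.2,86,3907,0.001,"published prevalence-by-cohort table, 1y underweight row, 2004 cohort"
1y,stunting,1982,8.5,123,1457,0.001,"published prevalence-by-cohort table, 1y stunting row, 1982 cohort"
1y,stunting,1993,9.2,182,1361,0.001,"published prevalence-by-cohort table, 1y stunting row, 1993 cohort"
1y,stunting,2004,6.0,232,3907,0.001,"published prevalence-by-cohort table, 1y stunting row, 2004 cohort"
1y,wasting,1982,2.1,30,1457,<0.001,"published prevalence-by-cohort table, 1y wasting row, 1982 cohort"
1y,wasting,1993,0.7,17,1361,<0.001,"published prevalence-by-cohort table, 1y wasting row, 1993 cohort"
1y,wasting,2004,0.6,25,3907,<0.001,"published prevalence-by-cohort table, 1y wasting row, 2004 cohort"
1y,overweight,1982,6.9,101,1457,0.107,"published prevalence-by-cohort table, 1y overweight row, 1982 cohort"
1y,overweight,1993,10.8,129,1361,0.107,"published prevalence-by-cohort table, 1y overweight row, 1993 cohort"
1y,overweight,2004,8.9,347,3907,0.107,"published prevalence-by-cohort table, 1y overweight row, 2004 cohort"
2y,underweight,1982,3.1,154,4939,0.001,"published prevalence-by-cohort table, 2y underweight row, 1982 cohort"
2y,underweight,2004,2.0,77,3869,0.001,"published prevalence-by-cohort table, 2y underweight row, 2004 cohort"
2y,stunting,1982,13.9,687,4939,<0.001,"published prevalence-by-cohort table, 2y stunting row, 1982 cohort"
2y,stunting,2004,5.0,192,3869,<0.001,"published prevalence-by-cohort table, 2y stunting row, 2004 cohort"
2y,wasting,1982,0.8,37,4939,0.995,"published prevalence-by-cohort table, 2y wasting row, 1982 cohort"
2y,wasting,2004,0.8,29,3869,0.995,"published prevalence-by-cohort table, 2y wasting row, 2004 cohort"
2y,overweight,1982,8.5,418,4939,0.781,"published prevalence-by-cohort table, 2y overweight row, 1982 cohort"
2y,overweight,2004,8.3,320,3869,0.781,"published prevalence-by-cohort table, 2y overweight row, 2004 cohort"
4y,underweight,1982,2.3,109,4742,0.051,"published prevalence-by-cohort table, 4y underweight row, 1982 cohort"
4y,underweight,1993,2.4,39,1243,0.051,"published prevalence-by-cohort table, 4y underweight row, 1993 cohort"
4y,underweight,2004,1.7,64,3799,0.051,"published prevalence-by-cohort table, 4y underweight row, 2004 cohort"
4y,stunting,1982,10.9,518,4742,<0.001,"published prevalence-by-cohort table, 4y stunting row, 1982 cohort"
4y,stunting,1993,5.3,92,1243,<0.001,"published prevalence-by-cohort table, 4y stunting row, 1993 cohort"
4y,stunting,2004,3.6,138,3799,<0.001,"published prevalence-by-cohort table, 4y stunting row, 2004 cohort"
4y,wasting,1982,0.3,16,4742,0.130,"published prevalence-by-cohort table, 4y wasting row, 1982 cohort"
4y,wasting,1993,0.4,10,1243,0.130,"published prevalence-by-cohort table, 4y wasting row, 1993 cohort"
4y,wasting,2004,0.6,21,3799,0.130,"published prevalence-by-cohort table, 4y wasting row, 2004 cohort"
4y,overweight,1982,7.6,358,4742,<0.001,"published prevalence-by-cohort table, 4y overweight row, 1982 cohort"
4y,overweight,1993,10.7,121,1243,<0.001,"published prevalence-by-cohort table, 4y overweight row, 1993 cohort"
4y,overweight,2004,12.3,463,3799,<0.001,"published prevalence-by-cohort table, 4y overweight row, 2004 cohort"
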