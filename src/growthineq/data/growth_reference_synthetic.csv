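indicator,sex,index_value,L,M,S
length_height_for_age,male,0.0,1.0,50.0,0.05
length_height_for_age,male,30.0,1.0,56.7934,0.04979
length_height_for_age,male,61.0,1.0,59.687,0.04957
length_height_for_age,male,91.0,1.0,61.8317,0.04935
length_height_for_age,male,122.0,1.0,63.6995,0.04913
length_height_for_age,male,152.0,1.0,65.2914,0.04892
length_height_for_age,male,183.0,1.0,66.7784,0.0487
length_height_for_age,male,274.0,1.0,70.5306,0.04805
length_height_for_age,male,365.0,1.0,73.6958,0.0474
length_height_for_age,male,456.0,1.0,76.4855,0.04675
length_height_for_age,male,548.0,1.0,79.0346,0.0461
length_height_for_age,male,639.0,1.0,81.3528,0.04545
length_height_for_age,male,730.0,1.0,83.511,0.0448
length_height_for_age,male,913.0,1.0,87.4767,0.0435
length_height_for_age,male,1096.0,1.0,91.0611,0.0422
length_height_for_age,male,1278.0,1.0,94.3395,0.0409
length_height_for_age,male,1461.0,1.0,97.4079,0.0396
length_height_for_age,male,1644.0,1.0,100.2894,0.0383
length_height_for_age,male,1826.0,1.0,103.0,0.037
bmi_for_age,male,0.0,1.0,13.3,0.13
bmi_for_age,male,30.0,0.98028,14.813,0.12934
bmi_for_age,male,61.0,0.95991,15.897,0.12866
bmi_for_age,male,91.0,0.9402,16.5884,0.12801
bmi_for_age,male,122.0,0.91982,17.0216,0.12733
bmi_for_age,male,152.0,0.90011,17.2357,0.12667
bmi_for_age,male,183.0,0.87974,17.3,0.12599
bmi_for_age,male,274.0,0.81993,16.9425,0.124
bmi_for_age,male,365.0,0.76013,16.2511,0.122
bmi_for_age,male,456.0,0.70033,15.5423,0.12001
bmi_for_age,male,548.0,0.63987,14.9299,0.118
bmi_for_age,male,639.0,0.58007,14.4559,0.116
bmi_for_age,male,730.0,0.52026,14.1031,0.11401
bmi_for_age,male,913.0,0.4,13.6695,0.11
bmi_for_age,male,1096.0,0.27974,13.4632,0.10599
bmi_for_age,male,1278.0,0.16013,13.3704,0.102
bmi_for_age,male,1461.0,0.03987,13.3296,0.098
bmi_for_age,male,1644.0,-0.08039,13.3123,0.09399
bmi_for_age,male,1826.0,-0.2,13.305,0.09
weight_for_age,male,0.0,0.3,3.325,0.11
weight_for_age,male,30.0,0.29836,4.7779,0.11033
weight_for_age,male,61.0,0.29666,5.6634,0.11067
weight_for_age,male,91.0,0.29502,6.342,0.111
weight_for_age,male,122.0,0.29332,6.9067,0.11134
weight_for_age,male,152.0,0.29168,7.3475,0.11166
weight_for_age,male,183.0,0.28998,7.7147,0.112
weight_for_age,male,274.0,0.28499,8.4281,0.113
weight_for_age,male,365.0,0.28001,8.8261,0.114
weight_for_age,male,456.0,0.27503,9.0923,0.11499
weight_for_age,male,548.0,0.26999,9.3259,0.116
weight_for_age,male,639.0,0.26501,9.5673,0.117
weight_for_age,male,730.0,0.26002,9.8356,0.118
weight_for_age,male,913.0,0.25,10.4602,0.12
weight_for_age,male,1096.0,0.23998,11.1638,0.122
weight_for_age,male,1278.0,0.23001,11.8996,0.124
weight_for_age,male,1461.0,0.21999,12.6475,0.126
weight_for_age,male,1644.0,0.20997,13.3894,0.12801
weight_for_age,male,1826.0,0.2,14.1153,0.13
weight_for_length_height,male,40.0,-0.2,2.128,0.09
weight_for_length_height,male,45.0,-0.2,2.6933,0.09
weight_for_length_height,male,50.0,-0.2,3.325,0.09
weight_for_length_height,male,55.0,-0.2,4.2905,0.09
weight_for_length_height,male,60.0,-0.2,5.7627,0.09
weight_for_length_height,male,65.0,-0.2,7.2703,0.09
weight_for_length_height,male,70.0,-0.2,8.3452,0.09
weight_for_length_height,male,75.0,-0.2,8.9558,0.09
weight_for_length_height,male,80.0,-0.2,9.4216,0.09
weight_for_length_height,male,85.0,-0.2,10.0498,0.09
weight_for_length_height,male,90.0,-0.2,10.9433,0.09
weight_for_length_height,male,95.0,-0.2,12.0563,0.09
weight_for_length_height,male,100.0,-0.2,13.3134,0.09
weight_for_length_height,male,105.0,-0.2,14.666,0.09
weight_for_length_height,male,110.0,-0.2,16.0935,0.09
weight_for_length_height,male,115.0,-0.2,17.5893,0.09
weight_for_length_height,male,120.0,-0.2,19.152,0.09
weight_for_length_height,male,125.0,-0.2,20.7813,0.09
length_height_for_age,female,0.0,1.0,49.2,0.05
length_height_for_age,female,30.0,1.0,55.8908,0.04979
length_height_for_age,female,61.0,1.0,58.7408,0.04957
length_height_for_age,female,91.0,1.0,60.8531,0.04935
length_height_for_age,female,122.0,1.0,62.6927,0.04913
length_height_for_age,female,152.0,1.0,64.2606,0.04892
length_height_for_age,female,183.0,1.0,65.7252,0.0487
length_height_for_age,female,274.0,1.0,69.4207,0.04805
length_height_for_age,female,365.0,1.0,72.5382,0.0474
length_height_for_age,female,456.0,1.0,75.2857,0.04675
length_height_for_age,female,548.0,1.0,77.7963,0.0461
length_height_for_age,female,639.0,1.0,80.0795,0.04545
length_height_for_age,female,730.0,1.0,82.2051,0.0448
length_height_for_age,female,913.0,1.0,86.111,0.0435
length_height_for_age,female,1096.0,1.0,89.6413,0.0422
length_height_for_age,female,1278.0,1.0,92.8702,0.0409
length_height_for_age,female,1461.0,1.0,95.8923,0.0396
length_height_for_age,female,1644.0,1.0,98.7303,0.0383
length_height_for_age,female,1826.0,1.0,101.4,0.037
bmi_for_age,female,0.0,1.0,13.034,0.13
bmi_for_age,female,30.0,0.98028,14.5167,0.12934
bmi_for_age,female,61.0,0.95991,15.579,0.12866
bmi_for_age,female,91.0,0.9402,16.2566,0.12801
bmi_for_age,female,122.0,0.91982,16.6812,0.12733
bmi_for_age,female,152.0,0.90011,16.891,0.12667
bmi_for_age,female,183.0,0.87974,16.954,0.12599
bmi_for_age,female,274.0,0.81993,16.6036,0.124
bmi_for_age,female,365.0,0.76013,15.9261,0.122
bmi_for_age,female,456.0,0.70033,15.2314,0.12001
bmi_for_age,female,548.0,0.63987,14.6313,0.118
bmi_for_age,female,639.0,0.58007,14.1668,0.116
bmi_for_age,female,730.0,0.52026,13.8211,0.11401
bmi_for_age,female,913.0,0.4,13.3961,0.11
bmi_for_age,female,1096.0,0.27974,13.1939,0.10599
bmi_for_age,female,1278.0,0.16013,13.103,0.102
bmi_for_age,female,1461.0,0.03987,13.063,0.098
bmi_for_age,female,1644.0,-0.08039,13.046,0.09399
bmi_for_age,female,1826.0,-0.2,13.0389,0.09
weight_for_age,female,0.0,0.3,3.1551,0.11
weight_for_age,female,30.0,0.29836,4.5347,0.11033
weight_for_age,female,61.0,0.29666,5.3755,0.11067
weight_for_age,female,91.0,0.29502,6.02,0.111
weight_for_age,female,122.0,0.29332,6.5563,0.11134
weight_for_age,female,152.0,0.29168,6.975,0.11166
weight_for_age,female,183.0,0.28998,7.3238,0.112
weight_for_age,female,274.0,0.28499,8.0017,0.113
weight_for_age,female,365.0,0.28001,8.3799,0.114
weight_for_age,female,456.0,0.27503,8.6331,0.11499
weight_for_age,female,548.0,0.26999,8.8553,0.116
weight_for_age,female,639.0,0.26501,9.0848,0.117
weight_for_age,female,730.0,0.26002,9.3399,0.118
weight_for_age,female,913.0,0.25,9.9334,0.12
weight_for_age,female,1096.0,0.23998,10.6021,0.122
weight_for_age,female,1278.0,0.23001,11.3012,0.124
weight_for_age,female,1461.0,0.21999,12.0119,0.126
weight_for_age,female,1644.0,0.20997,12.7168,0.12801
weight_for_age,female,1826.0,0.2,13.4066,0.13
weight_for_length_height,female,40.0,-0.2,2.0854,0.09
weight_for_length_height,female,45.0,-0.2,2.6394,0.09
weight_for_length_height,female,50.0,-0.2,3.2647,0.09
weight_for_length_height,female,55.0,-0.2,4.2938,0.09
weight_for_length_height,female,60.0,-0.2,5.7611,0.09
weight_for_length_height,female,65.0,-0.2,7.1566,0.09
weight_for_length_height,female,70.0,-0.2,8.0832,0.09
weight_for_length_height,female,75.0,-0.2,8.6082,0.09
weight_for_length_height,female,80.0,-0.2,9.0761,0.09
weight_for_length_height,female,85.0,-0.2,9.7479,0.09
weight_for_length_height,female,90.0,-0.2,10.676,0.09
weight_for_length_height,female,95.0,-0.2,11.7973,0.09
weight_for_length_height,female,100.0,-0.2,13.0419,0.09
weight_for_length_height,female,105.0,-0.2,14.3715,0.09
weight_for_length_height,female,110.0,-0.2,15.7714,0.09
weight_for_length_height,female,115.0,-0.2,17.2375,0.09
weight_for_length_height,female,120.0,-0.2,18.769,0.09
weight_for_length_height,female,125.0,-0.2,20.3656,0.09
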