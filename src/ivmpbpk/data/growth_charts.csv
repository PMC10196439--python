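age_years,sex,weight_median_kg,weight_cv,height_median_cm,height_cv
2,male,12.2,0.14,87.1,0.038
3,male,14.3,0.14,96.1,0.038
4,male,16.3,0.14,103.3,0.038
5,male,18.3,0.14,110.0,0.038
6,male,20.5,0.14,116.0,0.038
7,male,22.9,0.14,121.7,0.038
8,male,25.4,0.15,127.3,0.038
9,male,28.1,0.15,132.6,0.038
10,male,31.2,0.15,137.8,0.038
11,male,34.7,0.16,143.1,0.038
12,male,38.8,0.16,149.1,0.038
2,female,11.5,0.14,85.7,0.038
3,female,13.9,0.14,95.1,0.038
4,female,16.1,0.14,102.7,0.038
5,female,18.2,0.15,109.4,0.038
6,female,20.2,0.15,115.1,0.038
7,female,22.4,0.15,120.8,0.038
8,female,25.0,0.15,126.6,0.038
9,female,28.2,0.16,132.5,0.038
10,female,31.9,0.16,138.6,0.038
11,female,36.9,0.16,145.0,0.038
12,female,41.5,0.16,151.2,0.038
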