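date,group,analysis_duration_min,whale_class,age_class,n_focal_calls
2006-07-19,1,88,Adult Female 1,adult,0
2006-07-19,1,88,Adult Female 2,adult,20
2007-07-17,2,160,Male Calf,calf,3
2007-07-17,2,160,Mother,adult,0
2008-07-07,3,147,Adult Male,adult,8
2008-07-07,3,147,Adult Female,adult,13
2008-07-14,4,31,Adult Female,adult,44
2008-07-14,4,31,Adult Male,adult,11
2009-07-22,5,227,Female Calf,calf,15
2009-07-22,5,227,Mother,adult,19
2009-07-22,5,227,Adult Female,adult,78
2009-07-20,6,415,Adult Female,adult,330
2009-07-20,6,415,Female Calf,calf,302
2009-07-20,6,415,Mother,adult,133
2009-07-29,7,17,Adult Female,adult,0
2009-07-29,7,17,Adult Male,adult,6
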