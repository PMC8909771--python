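patient,target,size_cm,tip_distance_mm,time_to_target_min,modality
1,1,1.8,3.1,3.3,US
2,1,1.8,3.8,4.1,US
3,1,1.5,2.1,5.7,CT
3,2,1.7,2.4,3.2,CT
3,3,1.4,3.6,4.9,CT
3,4,1.2,2.7,4.2,CT
4,1,1.4,3.9,5.3,US
4,2,1.4,2.9,3.4,US
5,1,2.1,3.6,5.3,CT
6,1,1.8,2.4,4.0,CT
6,2,0.8,"2,2",4.2,CT
7,1,3.0,4.5,5.2,CT
8,1,1.5,4.1,3.3,US
8,2,1.2,3.1,3.6,US
8,3,0.7,3.4,4.9,US
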