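sample_id,colony_id,treatment,hours_after_t0,time_of_day,analysis_type,pct_c1_plus_s,pct_c2,pct_hyper
1,A,control,60,06:00,IFC,92.0,8.0,0.0
2,A,heat,60,06:00,IFC,91.6,7.5,0.8
3,A,control,114,12:00,IFC,94.0,5.3,0.7
4,B,heat,60,06:00,IFC,97.5,2.5,0.0
5,B,control,60,06:00,IFC,96.0,3.8,0.2
6,B,control,114,12:00,IFC,89.8,8.6,0.0
7,B,heat,114,12:00,IFC,82.3,16.4,1.3
8,C,control,60,06:00,IFC,94.8,4.8,0.4
9,C,heat,60,06:00,IFC,95.3,4.4,0.3
10,C,control,66,12:00,IFC,60.5,36.2,3.3
11,A,heat,78,00:00,sorting,88.5,7.8,2.0
12,A,heat,108,06:00,sorting,97.9,1.9,0.1
13,A,control,108,06:00,sorting,89.8,8.4,2.1
14,A,control,114,12:00,sorting,89.9,9.3,1.1
15,B,heat,78,00:00,sorting,82.9,9.5,4.7
16,B,control,108,06:00,sorting,86.4,11.5,1.3
17,C,control,108,06:00,sorting,94.2,4.9,0.8
18,C,heat,78,00:00,sorting,91.9,7.4,1.3
19,C,heat,108,06:00,sorting,96.0,3.4,0.7
20,C,control,72,18:00,sorting,91.1,5.9,2.0
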