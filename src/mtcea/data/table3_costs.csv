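window_start_month,window_end_month,group,treatment_category,total_cost_sek,n_patients
0,12,control,orthopaedics,106000,38
0,12,control,physiotherapy,178596,13
0,12,control,orthotics,1650,6
0,12,control,radiography_tests,37346,19
0,12,control,surgery,187439,7
0,12,control,drugs_injections,6933,18
0,12,control,paramedical,20790,5
0,12,index,specialised_MT,104580,40
0,12,index,orthopaedics,30000,15
0,12,index,physiotherapy,22878,2
0,12,index,orthotics,630,1
0,12,index,radiography_tests,19197,6
0,12,index,surgery,16340,1
0,12,index,drugs_injections,3141,3
0,12,index,paramedical,20054,5
12,96,control,specialised_MT,8190,2
12,96,control,orthopaedics,17936,4
12,96,control,physiotherapy,853392,11
12,96,control,orthotics,13248,1
12,96,control,surgery,72188,2
12,96,control,paramedical,312074,7
12,96,index,specialised_MT,2520,2
12,96,index,physiotherapy,23184,3
12,96,index,orthotics,1104,1
12,96,index,surgery,114890,5
12,96,index,paramedical,1600,1
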