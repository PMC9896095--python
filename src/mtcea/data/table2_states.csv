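follow_up_month,group,category,count,mean_utility
3,control,physiotherapy,13,0.651
3,control,orthopaedics,20,0.719
3,control,surgery,5,0.713
3,index,specialised_MT,40,0.737
6,control,physiotherapy,14,0.650
6,control,orthopaedics,2,0.796
6,control,recovered_no_treatment,13,0.791
6,control,non_recovered_no_treatment,9,0.728
6,index,orthopaedics,10,0.699
6,index,surgery,1,0.537
6,index,recovered_no_treatment,24,0.804
6,index,non_recovered_no_treatment,5,0.616
12,control,physiotherapy,10,0.643
12,control,orthopaedics,1,0.595
12,control,surgery,2,0.678
12,control,recovered_no_treatment,12,0.842
12,control,non_recovered_no_treatment,12,0.681
12,index,physiotherapy,2,0.606
12,index,recovered_no_treatment,29,0.812
12,index,non_recovered_no_treatment,7,0.586
96,control,physiotherapy,10,0.690
96,control,surgery,2,0.568
96,control,recovered_no_treatment,20,0.763
96,control,non_recovered_no_treatment,5,0.615
96,index,specialised_MT,2,0.808
96,index,physiotherapy,1,0.887
96,index,surgery,5,0.785
96,index,recovered_no_treatment,26,0.853
96,index,non_recovered_no_treatment,4,0.649
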