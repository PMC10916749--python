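subject_id,true_group,diagnosis,radiomics_score,cnn_score
pat-01,dementia,FTD,100,99.7
pat-02,dementia,DLB,92.3,98.7
pat-03,dementia,FTD,98.6,98.7
pat-04,dementia,MCI,93.9,91.8
pat-05,dementia,FTD,99.5,96.8
pat-06,dementia,AD,99.5,98.2
pat-07,dementia,FTD,98.4,91.7
pat-08,dementia,FTD,99.9,98
pat-09,dementia,AD,99.5,94
pat-10,dementia,FTD,93.8,88.1
hc-01,control,HC,99.6,77.3
hc-02,control,HC,97.9,93.5
hc-03,control,HC,99.3,86.8
hc-04,control,HC,94.1,97
hc-05,control,HC,97.6,88.4
hc-06,control,HC,100,85
hc-07,control,HC,95.5,81.1
hc-08,control,HC,96.7,80.9
hc-09,control,HC,100,83.7
hc-10,control,HC,99.8,84.1
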