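level,label,variant,monotone,n_total,n_without,pct_without,n_with,pct_with,decrease_n,decrease_pct,z
item,Nightmares,,True,975,247,25.3,146,15.0,101,40.7,10.05
item,Flashbacks,,True,975,242,24.8,172,17.6,70,29.0,8.37
item,Internal avoidance,,True,975,281,28.8,230,23.6,51,18.1,7.14
item,External avoidance,,True,975,268,27.5,185,19.0,83,30.9,9.11
item,Hyperalert,,True,975,320,32.8,179,18.4,41,43.9,11.87
item,Hyperarousal,,True,975,243,24.9,182,18.7,61,24.9,7.81
item,Functional impairment (PTSD),,True,975,267,27.4,192,19.7,75,28.1,8.66
item,Difficulty calming down,,True,975,347,35.6,257,26.4,90,25.8,9.49
item,Numbing,1,True,975,285,29.2,191,19.6,94,32.9,9.70
item,Numbing,2,True,975,285,29.2,209,21.4,76,26.7,8.72
item,Feel like a failure,,True,975,249,25.5,204,20.9,45,18.0,6.71
item,Feel worthless,,True,975,233,23.9,182,18.7,51,21.8,7.14
item,Feel cut off from others,1,True,975,274,28.1,221,22.7,53,19.2,7.28
item,Feel cut off from others,2,True,975,274,28.1,203,20.8,71,26.0,8.43
item,Difficult close to others,,True,975,271,27.8,209,21.4,62,23.0,7.87
item,Functional impairment (DSO),,True,975,282,28.9,204,20.9,78,27.7,8.83
cluster,Re-experiencing,,True,975,320,32.8,221,22.7,99,30.8,9.95
cluster,Avoidance,,True,975,353,36.2,286,29.3,67,19.1,8.19
cluster,Sense of threat,,True,975,367,37.6,235,24.1,132,35.9,11.49
cluster,PTSD functional impairment,,True,975,267,27.4,192,19.7,75,28.1,8.66
cluster,Affective dysregulation,,True,975,418,42.9,318,32.6,100,24.0,10.00
cluster,Negative self-concept,,True,975,295,30.3,238,24.4,57,19.5,7.55
cluster,Disturbed relationships,,True,975,350,35.9,268,27.5,82,23.4,9.06
cluster,DSO functional impairment,,True,975,282,28.9,204,20.9,78,27.7,8.83
disorder,PTSD,,False,975,53,5.4,37,3.8,16,29.6,2.17
disorder,CPTSD,,True,975,93,9.5,48,4.9,45,48.4,6.56
disorder,Either PTSD or CPTSD,,True,975,146,14.9,85,8.7,61,41.6,7.68
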