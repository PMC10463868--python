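term,dimension,level,decrement
constant,,,0.08
n3,,,0.15
dimension,mobility,2,0.06
dimension,mobility,3,0.25
dimension,self_care,2,0.09
dimension,self_care,3,0.22
dimension,usual_activities,2,0.04
dimension,usual_activities,3,0.12
dimension,pain_discomfort,2,0.10
dimension,pain_discomfort,3,0.30
dimension,anxiety_depression,2,0.07
dimension,anxiety_depression,3,0.20
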