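compound,overstandard_rate,detection_rate,max_mg_L,mean_mg_L
trichloroethylene,0.716,0.821,28,1.07
trichloromethane,0.269,0.418,0.95,0.08
carbon tetrachloride,0.104,0.119,0.021,0.00
vinyl chloride,0.612,0.627,1.92,0.15
"1,1-dichloroethane",0.552,0.806,26.5,2.01
"1,2-dichloroethane",0.045,0.403,0.06,0.01
"1,1,2-trichloroethane",0.537,0.612,1.08,0.09
"1,1-dichloroethylene",0.343,0.567,0.33,0.04
"1,2-dichloroethylene",0.522,0.716,17.6,0.72
tetrachloroethylene,0.313,0.657,0.45,0.05
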