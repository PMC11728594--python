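name,cas,sf_oral,iur,rfd_oral,rfc,henry_dimensionless,d_air,d_water,kp,abs_gi,detection_limit,standard_limit
trichloroethylene,79-01-6,0.046,4.1e-06,0.0005,0.002,0.403,0.079,9.1e-06,0.0116,1.0,0.0003,0.07
trichloromethane,67-66-3,0.031,2.3e-05,0.01,0.098,0.15,0.104,1.0e-05,0.00683,1.0,0.0014,0.06
carbon tetrachloride,56-23-5,0.04,3.0e-06,0.004,0.1,1.13,0.078,8.8e-06,0.0163,1.0,0.0015,0.002
vinyl chloride,75-01-4,0.72,4.4e-06,0.002,0.1,1.14,0.106,1.23e-05,0.0056,1.0,0.0008,0.005
"1,1-dichloroethane",75-34-3,0.0057,1.6e-06,0.2,,0.23,0.0742,1.05e-05,0.00617,1.0,0.0006,0.1
"1,2-dichloroethane",107-06-2,0.045,2.6e-05,0.006,0.007,0.048,0.104,9.9e-06,0.0053,1.0,0.0006,0.03
"1,1,2-trichloroethane",79-00-5,0.044,1.6e-05,0.004,0.0002,0.0337,0.078,8.8e-06,0.00553,1.0,0.0006,0.005
"1,1-dichloroethylene",75-35-4,,,0.05,0.2,1.07,0.09,1.04e-05,0.011,1.0,0.0012,0.03
"1,2-dichloroethylene",540-59-0,,,0.002,,0.167,0.0736,1.13e-05,0.00993,1.0,0.0012,0.05
tetrachloroethylene,127-18-4,0.0021,2.6e-07,0.006,0.04,0.724,0.072,8.2e-06,0.0333,1.0,0.0012,0.04
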