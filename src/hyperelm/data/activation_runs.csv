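database,activation,run,accuracy
polyu,sigmoid,1,100
polyu,sigmoid,2,99.9
polyu,sigmoid,3,99.9
polyu,sigmoid,4,99.97
polyu,sigmoid,5,99.93
polyu,sigmoid,6,100
polyu,sigmoid,7,99.9
polyu,sigmoid,8,99.93
polyu,sigmoid,9,99.97
polyu,sigmoid,10,100
polyu,sin,1,99.2
polyu,sin,2,98.83
polyu,sin,3,99.03
polyu,sin,4,99.13
polyu,sin,5,98.97
polyu,sin,6,99.0
polyu,sin,7,98.97
polyu,sin,8,99.2
polyu,sin,9,99.03
polyu,sin,10,98.97
polyu,atan,1,99.87
polyu,atan,2,99.7
polyu,atan,3,99.83
polyu,atan,4,99.83
polyu,atan,5,99.83
polyu,atan,6,99.93
polyu,atan,7,99.93
polyu,atan,8,99.87
polyu,atan,9,99.83
polyu,atan,10,99.93
casia,sigmoid,1,98.17
casia,sigmoid,2,98.33
casia,sigmoid,3,98.5
casia,sigmoid,4,98.0
casia,sigmoid,5,98.0
casia,sigmoid,6,98.17
casia,sigmoid,7,98.0
casia,sigmoid,8,98.5
casia,sigmoid,9,98.33
casia,sigmoid,10,98.17
casia,sin,1,97.5
casia,sin,2,97.67
casia,sin,3,97.5
casia,sin,4,97.83
casia,sin,5,97.67
casia,sin,6,97.5
casia,sin,7,97.33
casia,sin,8,97.83
casia,sin,9,97.67
casia,sin,10,97.83
casia,atan,1,97.67
casia,atan,2,97.83
casia,atan,3,97.67
casia,atan,4,97.67
casia,atan,5,97.83
casia,atan,6,97.5
casia,atan,7,98.0
casia,atan,8,97.67
casia,atan,9,97.83
casia,atan,10,97.83
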