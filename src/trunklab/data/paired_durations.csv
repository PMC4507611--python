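test,subject,traditional_s,sensor_s
STEET,1,43,32
STEET,2,56,59
STEET,3,59,108
STEET,4,121,123
STEET,5,104,99
STEET,6,48,60
STEET,7,98,105
STEET,8,123,117
STEET,9,59,52
STEET,10,75,85
TCSET,1,42,66
TCSET,2,79,74
TCSET,3,107,148
TCSET,4,112,99
TCSET,5,101,89
TCSET,6,79,59
TCSET,7,118,94
TCSET,8,78,79
TCSET,9,77,71
TCSET,10,154,144
SBET right,1,30,25
SBET right,2,31,20
SBET right,3,51,69
SBET right,4,38,44
SBET right,5,33,38
SBET right,6,34,36
SBET right,7,52,52
SBET right,8,55,46
SBET right,9,21,17
SBET right,10,39,62
SBET left,1,26,29
SBET left,2,28,30
SBET left,3,54,72
SBET left,4,46,52
SBET left,5,35,32
SBET left,6,30,34
SBET left,7,35,39
SBET left,8,46,45
SBET left,9,28,18
SBET left,10,25,55
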