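model,predicted,RSR,LSR,S
RF,RSR,2058,6,3
RF,LSR,0,1137,31
RF,S,1,59,4828
KNN,RSR,2047,3,25
KNN,LSR,0,1120,88
KNN,S,12,79,4749
XGB,RSR,2059,5,0
XGB,LSR,0,1167,29
XGB,S,0,30,4833
SVM,RSR,2055,9,0
SVM,LSR,0,1070,55
SVM,S,4,123,4807
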