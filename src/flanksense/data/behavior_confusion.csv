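model,predicted,feeding,moving,resting,ruminating,standing_still
RF,feeding,978,220,8,20,232
RF,moving,135,742,3,15,156
RF,resting,4,9,2412,204,8
RF,ruminating,1,6,65,570,11
RF,standing_still,310,265,13,140,1038
KNN,feeding,839,251,18,34,297
KNN,moving,202,643,18,29,218
KNN,resting,28,24,2296,219,52
KNN,ruminating,48,40,150,587,91
KNN,standing_still,311,284,19,80,787
XGB,feeding,896,202,5,21,280
XGB,moving,161,699,7,11,171
XGB,resting,3,13,2410,182,6
XGB,ruminating,8,20,69,595,21
XGB,standing_still,360,308,10,140,967
SVM,feeding,784,272,16,18,246
SVM,moving,115,516,10,7,110
SVM,resting,14,28,2334,286,59
SVM,ruminating,1,15,82,462,11
SVM,standing_still,514,411,59,176,1019
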