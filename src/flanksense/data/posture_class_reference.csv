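class,model,sensitivity,specificity,precision,npv,prevalence,balanced_accuracy
RSR,RF,1.00,0.999,0.996,1.00,0.253,0.999
LSR,RF,0.946,0.996,0.973,0.991,0.148,0.971
S,RF,0.993,0.982,0.988,0.989,0.599,0.987
RSR,KNN,0.994,0.995,0.987,0.998,0.253,0.995
LSR,KNN,0.932,0.987,0.927,0.988,0.148,0.960
S,KNN,0.977,0.972,0.981,0.966,0.599,0.974
RSR,XGB,1.00,0.999,0.998,1.00,0.253,1.00
LSR,XGB,0.971,0.996,0.976,0.995,0.148,0.983
S,XGB,0.994,0.991,0.994,0.991,0.599,0.992
RSR,SVM,0.998,0.999,0.996,0.999,0.253,0.998
LSR,SVM,0.890,0.992,0.951,0.981,0.148,0.941
S,SVM,0.989,0.961,0.974,0.983,0.599,0.975
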