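model,accuracy,kappa,accuracy_lower,accuracy_upper,p_value
RF,0.988,0.978,0.985,0.990,<0.001
KNN,0.974,0.954,0.971,0.978,<0.001
XGB,0.992,0.986,0.990,0.994,<0.001
SVM,0.976,0.957,0.973,0.980,<0.001
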