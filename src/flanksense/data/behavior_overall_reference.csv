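model,accuracy,kappa,accuracy_lower,accuracy_upper,p_value
RF,0.759,0.687,0.749,0.768,<0.001
KNN,0.681,0.587,0.670,0.692,<0.001
XGB,0.736,0.657,0.726,0.746,<0.001
SVM,0.676,0.578,0.665,0.687,<0.001
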