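class,model,sensitivity,specificity,precision,npv,prevalence,balanced_accuracy
feeding,RF,0.685,0.922,0.671,0.926,0.189,0.803
moving,RF,0.597,0.951,0.706,0.923,0.164,0.774
resting,RF,0.964,0.956,0.915,0.982,0.331,0.960
ruminating,RF,0.601,0.987,0.873,0.945,0.125,0.794
standing_still,RF,0.718,0.881,0.588,0.930,0.191,0.800
feeding,KNN,0.587,0.902,0.583,0.904,0.189,0.745
moving,KNN,0.518,0.926,0.579,0.907,0.164,0.722
resting,KNN,0.918,0.936,0.877,0.959,0.331,0.927
ruminating,KNN,0.618,0.950,0.641,0.946,0.125,0.784
standing_still,KNN,0.545,0.887,0.531,0.892,0.191,0.716
feeding,XGB,0.627,0.917,0.638,0.914,0.189,0.772
moving,XGB,0.563,0.945,0.666,0.917,0.164,0.754
resting,XGB,0.964,0.960,0.922,0.982,0.331,0.962
ruminating,XGB,0.627,0.982,0.834,0.948,0.125,0.805
standing_still,XGB,0.669,0.866,0.542,0.917,0.191,0.768
feeding,SVM,0.549,0.910,0.587,0.897,0.189,0.729
moving,SVM,0.415,0.962,0.681,0.893,0.164,0.689
resting,SVM,0.933,0.924,0.858,0.965,0.331,0.928
ruminating,SVM,0.487,0.983,0.809,0.930,0.125,0.735
standing_still,SVM,0.705,0.810,0.468,0.921,0.191,0.758
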