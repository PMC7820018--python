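feature,category,median_icc
wavelet-LLH_glcm_JointEnergy,WF,0.9822
log-sigma-2-0-mm-3D_glrlm_RunLengthNonUniformity,LOG,0.9766
log-sigma-3-0-mm-3D_glrlm_RunLengthNonUniformity,LOG,0.9724
original_gldm_DependenceNonUniformity,TA,0.9571
wavelet-LLH_glcm_Idm,WF,0.9542
log-sigma-3-0-mm-3D_firstorder_10Percentile,LOG,0.9484
log-sigma-3-0-mm-3D_glrlm_RunPercentage,LOG,0.9475
wavelet-LLH_glcm_Id,WF,0.9474
wavelet-LLH_glcm_SumEntropy,WF,0.9424
log-sigma-3-0-mm-3D_firstorder_Mean,LOG,0.9409
log-sigma-3-0-mm-3D_firstorder_Median,LOG,0.9386
log-sigma-2-0-mm-3D_glrlm_LongRunEmphasis,LOG,0.9379
log-sigma-2-0-mm-3D_gldm_LargeDependenceEmphasis,LOG,0.9374
log-sigma-2-0-mm-3D_firstorder_10Percentile,LOG,0.9372
wavelet-LLH_glrlm_GrayLevelNonUniformityNormalized,WF,0.9367
log-sigma-2-0-mm-3D_glrlm_RunVariance,LOG,0.9364
log-sigma-2-0-mm-3D_glrlm_RunPercentage,LOG,0.9361
log-sigma-3-0-mm-3D_glrlm_RunLengthNonUniformityNormalized,LOG,0.9352
original_glrlm_RunLengthNonUniformity,TA,0.9333
log-sigma-3-0-mm-3D_gldm_DependenceVariance,LOG,0.9326
wavelet-LLH_glrlm_RunLengthNonUniformityNormalized,WF,0.9322
log-sigma-3-0-mm-3D_glrlm_ShortRunEmphasis,LOG,0.9317
log-sigma-3-0-mm-3D_firstorder_RootMeanSquared,LOG,0.9314
wavelet-LLH_glrlm_RunPercentage,WF,0.9304
log-sigma-2-0-mm-3D_firstorder_Mean,LOG,0.9297
log-sigma-2-0-mm-3D_glrlm_ShortRunEmphasis,LOG,0.9295
wavelet-LLH_glrlm_ShortRunEmphasis,WF,0.9293
log-sigma-2-0-mm-3D_glrlm_RunLengthNonUniformityNormalized,LOG,0.9284
log-sigma-2-0-mm-3D_firstorder_Entropy,LOG,0.9284
wavelet-LHL_firstorder_10Percentile,WF,0.9280
log-sigma-1-0-mm-3D_gldm_LargeDependenceEmphasis,LOG,0.9274
wavelet-LHL_firstorder_InterquartileRange,WF,0.9270
wavelet-LHL_firstorder_MeanAbsoluteDeviation,WF,0.9258
log-sigma-1-0-mm-3D_glrlm_ShortRunEmphasis,LOG,0.9257
wavelet-LHL_firstorder_RobustMeanAbsoluteDeviation,WF,0.9255
wavelet-LHL_glcm_Imc2,WF,0.9252
wavelet-LHL_glcm_Idn,WF,0.9227
wavelet-LHL_glszm_SizeZoneNonUniformity,WF,0.9222
log-sigma-3-0-mm-3D_firstorder_MeanAbsoluteDeviation,LOG,0.9219
wavelet-LHL_glszm_ZonePercentage,WF,0.9216
log-sigma-2-0-mm-3D_firstorder_Kurtosis,LOG,0.9213
wavelet-LHL_gldm_SmallDependenceEmphasis,WF,0.9209
log-sigma-2-0-mm-3D_glcm_SumEntropy,LOG,0.9200
log-sigma-2-0-mm-3D_firstorder_RobustMeanAbsoluteDeviation,LOG,0.9198
log-sigma-3-0-mm-3D_firstorder_Kurtosis,LOG,0.9196
wavelet-LHL_ngtdm_Contrast,WF,0.9188
wavelet-LHL_ngtdm_Strength,WF,0.9182
wavelet-HLL_firstorder_10Percentile,WF,0.9174
wavelet-HLL_firstorder_Entropy,WF,0.9169
wavelet-HLL_firstorder_InterquartileRange,WF,0.9169
wavelet-HLL_firstorder_MeanAbsoluteDeviation,WF,0.9168
wavelet-HLL_firstorder_RobustMeanAbsoluteDeviation,WF,0.9167
log-sigma-2-0-mm-3D_glcm_JointEntropy,LOG,0.9163
wavelet-HLL_firstorder_Uniformity,WF,0.9162
wavelet-HLL_glcm_DifferenceAverage,WF,0.9157
wavelet-HLL_glcm_DifferenceEntropy,WF,0.9154
log-sigma-3-0-mm-3D_firstorder_Variance,LOG,0.9153
log-sigma-2-0-mm-3D_firstorder_RootMeanSquared,LOG,0.9142
log-sigma-2-0-mm-3D_firstorder_Uniformity,LOG,0.9139
log-sigma-2-0-mm-3D_glcm_Id,LOG,0.9138
log-sigma-2-0-mm-3D_glcm_Idm,LOG,0.9137
wavelet-HLL_glcm_JointEntropy,WF,0.9134
wavelet-HLL_glcm_Idm,WF,0.9132
wavelet-HLL_glcm_Idmn,WF,0.9131
wavelet-HLL_glcm_Id,WF,0.9131
wavelet-HLL_glcm_Idn,WF,0.9130
wavelet-HLL_glcm_MaximumProbability,WF,0.9123
log-sigma-2-0-mm-3D_firstorder_MeanAbsoluteDeviation,LOG,0.9120
wavelet-HLL_glcm_SumEntropy,WF,0.9119
log-sigma-1-0-mm-3D_glrlm_RunPercentage,LOG,0.9115
wavelet-HLL_glrlm_GrayLevelNonUniformityNormalized,WF,0.9114
wavelet-HLL_glrlm_RunLengthNonUniformityNormalized,WF,0.9112
log-sigma-2-0-mm-3D_firstorder_InterquartileRange,LOG,0.9110
wavelet-HLL_glrlm_RunPercentage,WF,0.9109
wavelet-HLL_glrlm_RunVariance,WF,0.9107
wavelet-HLL_glrlm_ShortRunEmphasis,WF,0.9105
wavelet-HLL_glszm_LargeAreaEmphasis,WF,0.9098
wavelet-HLL_glszm_ZonePercentage,WF,0.9098
wavelet-HLL_glszm_ZoneVariance,WF,0.9092
wavelet-HLL_gldm_LargeDependenceEmphasis,WF,0.9089
wavelet-HLL_gldm_SmallDependenceEmphasis,WF,0.9089
original_gldm_SmallDependenceEmphasis,TA,0.9084
log-sigma-2-0-mm-3D_glcm_JointEnergy,LOG,0.9082
wavelet-HLL_ngtdm_Contrast,WF,0.9074
wavelet-HHL_glrlm_RunPercentage,WF,0.9073
wavelet-HHL_gldm_LargeDependenceEmphasis,WF,0.9069
log-sigma-3-0-mm-3D_firstorder_RobustMeanAbsoluteDeviation,LOG,0.9059
wavelet-LLL_firstorder_Entropy,WF,0.9056
log-sigma-1-0-mm-3D_firstorder_RobustMeanAbsoluteDeviation,LOG,0.9055
wavelet-LLL_firstorder_RootMeanSquared,WF,0.9051
wavelet-LLL_glcm_Contrast,WF,0.9051
wavelet-LLL_glcm_DifferenceAverage,WF,0.9044
log-sigma-3-0-mm-3D_firstorder_InterquartileRange,LOG,0.9042
log-sigma-2-0-mm-3D_glrlm_GrayLevelNonUniformityNormalized,LOG,0.9039
log-sigma-2-0-mm-3D_glcm_DifferenceAverage,LOG,0.9039
wavelet-LLL_glcm_DifferenceEntropy,WF,0.9037
wavelet-LLL_glcm_JointEntropy,WF,0.9036
log-sigma-2-0-mm-3D_glcm_DifferenceEntropy,LOG,0.9036
log-sigma-1-0-mm-3D_glcm_Id,LOG,0.9035
wavelet-LLL_glcm_Idm,WF,0.9032
log-sigma-1-0-mm-3D_glrlm_RunLengthNonUniformityNormalized,LOG,0.9031
wavelet-LLL_glcm_Id,WF,0.9031
log-sigma-1-0-mm-3D_firstorder_InterquartileRange,LOG,0.9026
wavelet-LLL_glcm_Idn,WF,0.9025
log-sigma-1-0-mm-3D_firstorder_10Percentile,LOG,0.9015
wavelet-LLL_gldm_DependenceNonUniformity,WF,0.9009
wavelet-LLL_gldm_DependenceNonUniformityNormalized,WF,0.9005
wavelet-LLL_gldm_SmallDependenceEmphasis,WF,0.9001
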