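t2w_hist_mean
t2w_hist_sd
t2w_hist_variance
t2w_hist_skewness
t2w_hist_kurtosis
t2w_hist_min
t2w_hist_max
t2w_hist_range
t2w_hist_median
t2w_hist_p10
t2w_hist_p25
t2w_hist_p75
t2w_hist_p90
t2w_hist_entropy
t2w_hist_uniformity
t2w_glcm_energy
t2w_glcm_entropy
t2w_glcm_correlation
t2w_glcm_contrast
t2w_glcm_homogeneity
t2w_glcm_dissimilarity
t2w_glcm_cluster_shade
t2w_glcm_cluster_prominence
t2w_glcm_max_probability
t2w_glcm_sum_average
t2w_glcm_sum_variance
t2w_glcm_sum_entropy
t2w_glcm_difference_average
t2w_glcm_difference_variance
t2w_glcm_difference_entropy
t2w_glcm_autocorrelation
t2w_glcm_joint_mean
t2w_glcm_joint_variance
t2w_glcm_inverse_difference
t2w_glcm_inverse_difference_norm
t2w_gldm_mean
t2w_gldm_variance
t2w_gldm_entropy
t2w_gldm_energy
t2w_gldm_contrast
t2w_gldm_inverse_difference_moment
t2w_gldm_max_probability
t2w_gldm_zero_fraction
t2w_fft_total_power
t2w_fft_spectral_entropy
t2w_fft_band1_fraction
t2w_fft_band2_fraction
t2w_fft_band3_fraction
t2w_fft_band4_fraction
t2w_fft_dominant_radial_freq
t2w_fft_mean_radial_freq
t2w_fft_radial_freq_sd
t2w_fft_spectral_flatness
t2w_fft_anisotropy
t2w_fft_low_high_ratio
adc_hist_mean
adc_hist_sd
adc_hist_variance
adc_hist_skewness
adc_hist_kurtosis
adc_hist_min
adc_hist_max
adc_hist_range
adc_hist_median
adc_hist_p10
adc_hist_p25
adc_hist_p75
adc_hist_p90
adc_hist_entropy
adc_hist_uniformity
adc_glcm_energy
adc_glcm_entropy
adc_glcm_correlation
adc_glcm_contrast
adc_glcm_homogeneity
adc_glcm_dissimilarity
adc_glcm_cluster_shade
adc_glcm_cluster_prominence
adc_glcm_max_probability
adc_glcm_sum_average
adc_glcm_sum_variance
adc_glcm_sum_entropy
adc_glcm_difference_average
adc_glcm_difference_variance
adc_glcm_difference_entropy
adc_glcm_autocorrelation
adc_glcm_joint_mean
adc_glcm_joint_variance
adc_glcm_inverse_difference
adc_glcm_inverse_difference_norm
adc_gldm_mean
adc_gldm_variance
adc_gldm_entropy
adc_gldm_energy
adc_gldm_contrast
adc_gldm_inverse_difference_moment
adc_gldm_max_probability
adc_gldm_zero_fraction
adc_fft_total_power
adc_fft_spectral_entropy
adc_fft_band1_fraction
adc_fft_band2_fraction
adc_fft_band3_fraction
adc_fft_band4_fraction
adc_fft_dominant_radial_freq
adc_fft_mean_radial_freq
adc_fft_radial_freq_sd
adc_fft_spectral_flatness
adc_fft_anisotropy
adc_fft_low_high_ratio
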