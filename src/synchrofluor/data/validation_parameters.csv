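# Reported regression and validation parameters of the reference method,
# stored for documentation/diffing only: slope, intercept and LOD/LOQ are
# instrument-specific and cannot be regenerated without the raw spectra.
parameter,FEX,PSE
wavelength_nm,286,294
linearity_low_ng_ml,100,50
linearity_high_ng_ml,1500,1000
lod_ng_ml,24.15,12.88
loq_ng_ml,73.49,39.21
slope,0.0377,0.0623
intercept,9.6551,8.8644
r_squared,0.9995,0.9994
accuracy_recovery,99.13,98.46
repeatability_rsd,1.369,0.493
intermediate_precision_rsd,1.012,1.207
robustness_delta_lambda_mean,100.63,99.20
robustness_delta_lambda_rsd,0.926,1.017
robustness_ph_mean,99.98,99.82
robustness_ph_rsd,1.066,1.314
robustness_buffer_volume_mean,100.89,100.12
robustness_buffer_volume_rsd,0.878,0.950
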