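name,tau_f_ns,sigma_exc_cm2,kisc_per_us,kT_per_us,kred_per_us,kox_per_us
CFl,4.04,3e-16,10.8,0.71,0.00001,0.00124
CFl-1Br,2.71,2.52e-16,94.5,0.61,0.0000104,0.000433
CFl-2Br,1.77,1.77e-16,309,0.61,0.00047,0.000238
CFl-4Br,1.12,1.65e-16,893,0.58,0.005,0.00001
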