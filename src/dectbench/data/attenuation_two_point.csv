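# Two-point linear attenuation reference table (NIST mass-attenuation
# coefficients times nominal densities). Columns mu_* are linear attenuation
# in 1/cm. e1/e2 are the fit points for the photoelectric + Klein-Nishina
# two-basis parameterization; e_check/mu_check is an independent mid-range
# check point used only by tests.
material,density_g_cm3,e1_kev,mu1_cm1,e2_kev,mu2_cm1,e_check_kev,mu_check_cm1
water,1.000,40.0,0.26830,80.0,0.18370,70.0,0.19320
bone,1.500,40.0,0.99825,80.0,0.33435,70.0,0.39240
polyethylene,0.930,40.0,0.21158,80.0,0.16954,70.0,0.17586
acrylic,1.190,40.0,0.27965,80.0,0.20837,70.0,0.21777
air,0.001205,40.0,0.00029944,80.0,0.00020027,70.0,0.00021196
aluminum,2.699,40.0,1.53438,80.0,0.54466,70.0,0.63184
steel,7.870,40.0,28.56023,80.0,4.68422,70.0,6.49826
adipose,0.950,40.0,0.22762,80.0,0.17072,70.0,0.17860
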