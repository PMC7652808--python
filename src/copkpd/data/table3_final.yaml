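# Final population estimates of the joint propofol-fentanyl-CO-BIS model.
# Volumes in L, clearances in L/min, ce50_p in mg/L, ce50_f in ng/mL,
# ke0 in 1/min, co0 in L/min, alpha_co in (L/min)/h, betas in percent.
# iiv_cv_percent holds inter-individual variability as %CV of a log-normal;
# it is converted to omega^2 = log(1 + (CV/100)^2) on load.
vc_p: 2.42
cl_p: 1.54
q1_p: 1.89
q2_p: 0.607
vt1_p: 54.4
vt2_p: 482.0
vc_f: 25.8
cl_f: 0.569
q1_f: 5.78
q2_f: 1.48
vt1_f: 98.9
vt2_f: 478.0
bis0: 88.6
emax: 1.0
gamma: 1.0
alpha_int: 0.0
ce50_p: 2.25
ce50_f: 8.77
ke0: 0.105
co0: 5.59
alpha_co: 1.09
co_ref: 6.5
co_plateau_time: 300.0
beta_age: -3.23
beta_study: -50.9
age_ref: 64.0
iiv_cv_percent:
  vc_p: 119.0
  cl_p: 37.7
  q1_p: 92.1
  vt1_p: 48.5
  vc_f: 37.7
  cl_f: 52.2
  q1_f: 54.3
  vt1_f: 42.0
  ce50_p: 46.9
  ce50_f: 122.0
  ke0: 134.0
  co0: 19.2
  alpha_co: 42.8
sigma_prop_p: 0.386
sigma_prop_f: 0.310
sigma_bis: 8.42
sigma_co: 1.41
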