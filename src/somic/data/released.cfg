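# SOMic released parameter set.
# Rates are month-1; pools and K_m are t C ha-1.
# Pinned to the reported calibration: MAC base MRT 5.5 y at 20 degC and
# 17 y at 10 degC (fixes q10 = 17/5.5 and k4 = 1/(66*sqrt(q10))),
# CUE(15 degC) = 0.28 with slope -0.0081 per degC.
k1 = 0.83
k2 = 0.025
k3 = 2.0
k4 = 0.008618128166583652
k5 = 0.2
f_s = 0.5
temp_form = q10
q10 = 3.090909090909091
t_ref = 15.0
w_min = 0.2
k_m = 0.45
s0 = 0.05
s1 = 1.5
cue_ref = 0.28
cue_slope = -0.0081
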