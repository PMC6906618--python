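# gaitmon linear speed model (synthetic-calibrated on the built-in simulator)
# n_train = 2760
# speed_range_mps = (0.3144718757206298, 1.1964265158944691)
# residual_std_mps = 0.028376155579212626
# seed = 0
term,coefficient
intercept,-0.03988156921694145
v_max,3.0
include_threeway,0
include_freq,0
A_x,2.3370626428837142
A_y,-1.4414787149276271
A_z,1.7486458136839989
A_xA_y,2.9546352743291986
A_xA_z,-7.003306684156816
A_yA_z,12.831391593928739
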