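units:
  voltages: mV
  time: ms (rate constants stored in literature s-based units, converted at load)
  concentrations: mM
  volumes: nL
  currents: pA
  conductances: nS
  permeability P_Na: nL/s
  diffusion coefficients: um^2/s
  capacitance: nF
constants:
  F: 96478.0
  R: 8314.0
  T: 306.15
  Na_o: 130.0
  Ca_o: 1.8
  K_o: 5.4
C_m: 0.05
P_Na: 0.0016
g_CaL: 19.75
E_Ca_app: 60.0
k_fca: 0.001
n_fca: 2.0
tau_fca: 0.002
g_to: 8.25
g_sus: 2.25
g_Ks: 1.0
g_Kr: 0.5
g_K1: 3.9
g_f: 1.0
f_f_Na: 0.2677
I_NaK_max: 70.8253
k_NaK_K: 1.0
k_NaK_Na: 11.0
k_NCX: 0.0095
gamma_NCX: 0.45
d_NCX: 0.0003
I_PMCA_max: 2.0
k_PMCA: 0.0005
g_Nab: 0.060599
g_Cab: 0.0952
BCa: 0.024
K_dBCa: 0.00238
SLlow: 165.0
K_dSLlow: 1.1
SLhigh: 13.0
K_dSLhigh: 0.013
CSQN: 6.7
K_dCSQN: 0.8
D_Ca: 780.0
D_CaBm: 25.0
D_CaSR: 44.0
D_Na: 0.12
serca_K_mf: 0.00025
serca_K_mr: 1.8
serca_k4: 18.0
serca_cpumps: 0.04
ryr_tau_act_ss: 0.005
ryr_tau_inact_ss: 0.015
ryr_tau_act_bulk: 0.04
ryr_tau_inact_bulk: 0.05
ryr_tau_adapt: 1.0
ryr_nu_ss: 375.0
ryr_nu_bulk: 4.75
ryr_a_base: 0.505
ryr_a_amp: 0.427
ryr_a_mid: 0.29
ryr_a_slope: 0.082
ryr_o_shift: 0.16
ryr_o_slope: 0.03
ryr_c_shift: 0.02
ryr_c_slope: 0.01
ryr_srca_mid: 0.3
ryr_srca_slope: 0.1
k_SRleak: 0.006
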