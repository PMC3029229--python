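{
 "variant": "vCa",
 "protocol": "1 Hz pacing, 600 s from seed_state()",
 "state": {
  "V": -76.93499644411035,
  "m": 0.0023113643426728218,
  "h1": 0.9256482479094886,
  "h2": 0.9242157118138389,
  "d": 8.183765198997212e-06,
  "f1": 0.9990718985045679,
  "f2": 0.9990730813722825,
  "fca": 0.9784677361952013,
  "r_to": 0.0008367571616306121,
  "s_to": 0.9597734256704398,
  "r_sus": 0.00011384300252463793,
  "s_sus": 0.994836259815787,
  "n_ks": 0.003921637931136217,
  "pa_kr": 3.271395365463537e-05,
  "y_f": 0.062490425553727726,
  "Na_i": 9.119450086226298,
  "K_i": 134.19873498189244,
  "Na_ss": 9.3,
  "Ca_ss": 0.0001483722156415483,
  "Ca_bulk1": 0.00011696335759999173,
  "Ca_bulk2": 0.0001190774367238688,
  "Ca_bulk3": 0.00012526236011571474,
  "Ca_bulk4": 0.00014064791555938727,
  "Ca_sr1": 0.6316137506839022,
  "Ca_sr2": 0.6256867661400359,
  "Ca_sr3": 0.6154230944574667,
  "Ca_sr4": 0.6017248751771387,
  "serca_ca1": 0.004578476692467637,
  "serca_ca2": 0.004515310587414029,
  "serca_ca3": 0.004425720282112268,
  "serca_ca_ss": 0.004445153903717253,
  "ryr_o1": 0.0006344678709888326,
  "ryr_c1": 0.9997000965543223,
  "ryr_a1": 0.1754791692853935,
  "ryr_o2": 0.0005935542113942953,
  "ryr_c2": 0.9997545166742972,
  "ryr_a2": 0.1794466665595098,
  "ryr_o3": 0.0005065577562881778,
  "ryr_c3": 0.9998472633216775,
  "ryr_a3": 0.19006185336652806,
  "ryr_oss": 0.0004425991126455248,
  "ryr_css": 0.9999039387278562,
  "ryr_ass": 0.21959167146663938
 }
}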