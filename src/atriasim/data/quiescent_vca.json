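{
 "variant": "vCa",
 "protocol": "quiescent (unpaced) steady state, relaxed 40 min from the paced state",
 "state": {
  "V": -74.5389768112298,
  "m": 0.003092252510947995,
  "h1": 0.8873504061145207,
  "h2": 0.8873504061049291,
  "d": 1.2374954043520245e-05,
  "f1": 0.9986937562229652,
  "f2": 0.9986937562229324,
  "fca": 0.976321198249028,
  "r_to": 0.0010403265983795118,
  "s_to": 0.9507298263557928,
  "r_sus": 0.0001537741043468576,
  "s_sus": 0.9982954580801604,
  "n_ks": 0.0005892091824287416,
  "pa_kr": 4.902344884356974e-05,
  "y_f": 0.13399020248135818,
  "Na_i": 8.12094807449825,
  "K_i": 135.23883913607727,
  "Na_ss": 9.3,
  "Ca_ss": 0.00015573402248904048,
  "Ca_bulk1": 0.000110097762174747,
  "Ca_bulk2": 0.00011400966044091849,
  "Ca_bulk3": 0.00012382969707150994,
  "Ca_bulk4": 0.00014524870496378323,
  "Ca_sr1": 0.4328995918803789,
  "Ca_sr2": 0.4289089042619075,
  "Ca_sr3": 0.4189035916173532,
  "Ca_sr4": 0.39714167269291334,
  "serca_ca1": 0.0024711356068947885,
  "serca_ca2": 0.0024650105289185415,
  "serca_ca3": 0.0024556431748443213,
  "serca_ca_ss": 0.0025693314048450913,
  "ryr_o1": 0.003364963497372473,
  "ryr_c1": 0.9557610612705618,
  "ryr_a1": 0.12082678795212504,
  "ryr_o2": 0.0036006898534449217,
  "ryr_c2": 0.9462959991918835,
  "ryr_a2": 0.12270033957892212,
  "ryr_o3": 0.004222165909644339,
  "ryr_c3": 0.9160252513081437,
  "ryr_a3": 0.12772497495353893,
  "ryr_oss": 0.006307565053279731,
  "ryr_css": 0.7647740818599772,
  "ryr_ass": 0.14752436315109313
 }
}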