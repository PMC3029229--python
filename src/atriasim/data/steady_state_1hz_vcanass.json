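{
 "variant": "vCaNass",
 "protocol": "1 Hz pacing, 600 s from seed_state()",
 "state": {
  "V": -76.43209249295279,
  "m": 0.0024570100133108736,
  "h1": 0.9191311625128129,
  "h2": 0.9191971700869853,
  "d": 8.922808997228844e-06,
  "f1": 0.9990070368713533,
  "f2": 0.9990124424712274,
  "fca": 0.9799279723194544,
  "r_to": 0.0008757954514315964,
  "s_to": 0.9581884740637107,
  "r_sus": 0.00012114074661968571,
  "s_sus": 0.9949710166430741,
  "n_ks": 0.003856580272135198,
  "pa_kr": 3.544922920406486e-05,
  "y_f": 0.06273835974654202,
  "Na_i": 9.155603477027705,
  "K_i": 134.16654383942407,
  "Na_ss": 8.618583212443257,
  "Ca_ss": 0.00014312388710996282,
  "Ca_bulk1": 0.0001157143406772517,
  "Ca_bulk2": 0.00011751160336731993,
  "Ca_bulk3": 0.0001228856767816714,
  "Ca_bulk4": 0.00013644069740585484,
  "Ca_sr1": 0.6291064543812803,
  "Ca_sr2": 0.6230923130052318,
  "Ca_sr3": 0.612724794059842,
  "Ca_sr4": 0.5994024553927317,
  "serca_ca1": 0.004543086820672871,
  "serca_ca2": 0.004477248188931762,
  "serca_ca3": 0.004381030336343755,
  "serca_ca_ss": 0.0043787549730791905,
  "ryr_o1": 0.0006194043868395055,
  "ryr_c1": 0.9997206717033609,
  "ryr_a1": 0.17507706674544102,
  "ryr_o2": 0.0005738297246527893,
  "ryr_c2": 0.9997779195366067,
  "ryr_a2": 0.17904532110908716,
  "ryr_o3": 0.0004773433555027639,
  "ryr_c3": 0.9998719601241575,
  "ryr_a3": 0.18967306744245419,
  "ryr_oss": 0.0003755474948783149,
  "ryr_css": 0.999940890118637,
  "ryr_ass": 0.21931579631508988
 }
}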