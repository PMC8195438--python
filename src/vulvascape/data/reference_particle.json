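{
 "description": "Parameter vector from this package's own desk-scale ABC SMC fit to the training conditions (a stand-in for a full-scale posterior particle), with one-dimensional perturbation-strength fits conditional on it.",
 "fit": {
  "n_particles": 256,
  "n_generations": 14,
  "n_reps": 16,
  "seed": 1,
  "epsilons": [
   4.0,
   3.092511111111111,
   1.9813999999999998,
   1.6263999999999998,
   1.1174888888888888,
   0.7491777777777778,
   0.7491777777777777,
   0.5408444444444443,
   0.4991777777777777,
   0.45751111111111104,
   0.41584444444444446,
   0.38806666666666667,
   0.3741777777777778,
   0.3602888888888889
  ],
  "gamma_mean": 0.22488674353397767,
  "gamma_sd": 0.0003619376848796926
 },
 "parameters": {
  "tau": 18.5732309822186,
  "m11": 0.08184202036490393,
  "m12": -0.29719440739797226,
  "m21": 0.6460954459479049,
  "m22": -0.30686496375153594,
  "m31": 0.6393938741156926,
  "m32": 0.19685626527112582,
  "q1": -2.068215829530755,
  "q2": 0.0780255174334612,
  "q3": -0.9408622960962078,
  "M": 2.327332057472112,
  "s": 4.448964798595768,
  "l": 5.3645327995962,
  "gamma": 0.2218938608031637,
  "H_E": 9.088599351690123,
  "M_E": -4.96742236109899,
  "n0": -2.21934602858967,
  "n1": 5.208185355852555,
  "alpha": 0.9801658216959992,
  "l_d": 0.5088056112893986,
  "sigma_dif": 0.2733379011864282,
  "lambda": 11.305093230906856
 },
 "modifiers": {
  "ju1100_dose": 3.2382606277628008,
  "notch_reduction": 0.609375,
  "ectopic_notch": 0.015625,
  "egf_hypomorph": 0.3984375
 }
}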