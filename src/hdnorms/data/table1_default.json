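{
  "age": {
    "mean": 46.99,
    "sd": 14.61,
    "low": 18.0,
    "high": 86.0
  },
  "education": {
    "mean": 14.66,
    "sd": 3.27,
    "low": 1.0,
    "high": 24.0
  },
  "p_female": 0.6054484236302418,
  "language_freqs": {
    "en": 0.5534129170492806,
    "de": 0.19559228650137742,
    "es": 0.09152127333945516,
    "it": 0.07284970921334558,
    "pl": 0.02999693908784818,
    "fr_ca": 0.021426385062748698,
    "nl": 0.014080195898377716,
    "es_la": 0.008876645240281604,
    "fr": 0.006427915518824609,
    "da": 0.0058157330884603614
  },
  "hand_freqs": {
    "r": 0.898,
    "l": 0.077,
    "mixed": 0.025
  },
  "language_by_age_shift": {},
  "hads_lambda": 2.5,
  "mmse_p": 0.82
}
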