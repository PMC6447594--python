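{
  "T": 10,
  "phi": 0.6,
  "K": 2000,
  "n_cv_folds": 3,
  "max_iter": 150,
  "tol": 1e-4,
  "seed": 7
}
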