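{
 "decoys": [
  {
   "family": "dimple",
   "params": {
    "r_o": 0.25,
    "sigma": 0.05,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.5,
    "sigma": 0.03,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.75,
    "sigma": 0.05,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.0052137144421794375
   },
   "target_nd": 1000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 4,
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.05157778105571706
   },
   "target_nd": 1000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 8,
    "r_o": 0.5,
    "sigma": 0.05,
    "A": 0.05157778105571706
   },
   "target_nd": 1000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 8,
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.03743739515259272
   },
   "target_nd": 1000
  },
  {
   "family": "sine",
   "params": {
    "m": 1,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "sine",
   "params": {
    "m": 2,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "sine",
   "params": {
    "m": 4,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "sine",
   "params": {
    "m": 8,
    "A": 0.03162277660168379
   },
   "target_nd": 1000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 1.0505400481198435,
    "beta": 0.9589331861290986
   },
   "target_nd": 1000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 0.9589331861290987,
    "beta": 1.0505400481198433
   },
   "target_nd": 1000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 1.2447086057285788,
    "beta": 1.2447086057285788
   },
   "target_nd": 1000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 0.8084639322758108,
    "beta": 0.8084639322758108
   },
   "target_nd": 1000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.25,
    "sigma": 0.05,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.5,
    "sigma": 0.03,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.75,
    "sigma": 0.05,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.35,
    "sigma": 0.05,
    "A": 0.0008243606353500641
   },
   "target_nd": 10000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.001648721270700128
   },
   "target_nd": 10000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.65,
    "sigma": 0.05,
    "A": 0.0008243606353500641
   },
   "target_nd": 10000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 4,
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.016310326479354993
   },
   "target_nd": 10000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 8,
    "r_o": 0.5,
    "sigma": 0.05,
    "A": 0.016310326479354993
   },
   "target_nd": 10000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 8,
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.011838743834593995
   },
   "target_nd": 10000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 16,
    "r_o": 0.5,
    "sigma": 0.05,
    "A": 0.011838744164342635
   },
   "target_nd": 10000
  },
  {
   "family": "sine",
   "params": {
    "m": 1,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "sine",
   "params": {
    "m": 2,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "sine",
   "params": {
    "m": 4,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "sine",
   "params": {
    "m": 8,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "sine",
   "params": {
    "m": 16,
    "A": 0.01
   },
   "target_nd": 10000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 1.0157080519316461,
    "beta": 0.986831454281545
   },
   "target_nd": 10000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 0.9868314542815448,
    "beta": 1.0157080519316466
   },
   "target_nd": 10000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 1.0708590087884104,
    "beta": 1.0708590087884104
   },
   "target_nd": 10000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 0.9344163883462872,
    "beta": 0.9344163883462872
   },
   "target_nd": 10000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.25,
    "sigma": 0.05,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.5,
    "sigma": 0.03,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "dimple",
   "params": {
    "r_o": 0.75,
    "sigma": 0.05,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.35,
    "sigma": 0.05,
    "A": 0.00026068572210897193
   },
   "target_nd": 100000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.0005213714442179438
   },
   "target_nd": 100000
  },
  {
   "family": "pulse",
   "params": {
    "r_o": 0.65,
    "sigma": 0.05,
    "A": 0.00026068572210897193
   },
   "target_nd": 100000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 4,
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.005157778105571706
   },
   "target_nd": 100000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 8,
    "r_o": 0.5,
    "sigma": 0.05,
    "A": 0.005157778105571706
   },
   "target_nd": 100000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 8,
    "r_o": 0.5,
    "sigma": 0.1,
    "A": 0.003743739515259272
   },
   "target_nd": 100000
  },
  {
   "family": "wavelet",
   "params": {
    "m": 16,
    "r_o": 0.5,
    "sigma": 0.05,
    "A": 0.003743739619534948
   },
   "target_nd": 100000
  },
  {
   "family": "sine",
   "params": {
    "m": 1,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "sine",
   "params": {
    "m": 2,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "sine",
   "params": {
    "m": 4,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "sine",
   "params": {
    "m": 8,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "sine",
   "params": {
    "m": 16,
    "A": 0.003162277660168379
   },
   "target_nd": 100000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 1.0049407339641505,
    "beta": 0.9958169741855323
   },
   "target_nd": 100000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 0.9958169741855328,
    "beta": 1.0049407339641498
   },
   "target_nd": 100000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 1.0218133256464599,
    "beta": 1.0218133256464599
   },
   "target_nd": 100000
  },
  {
   "family": "beta",
   "params": {
    "alpha": 0.9787137980956025,
    "beta": 0.9787137980956025
   },
   "target_nd": 100000
  },
  {
   "family": "reduced",
   "params": {
    "p": 0.05
   },
   "target_nd": null
  },
  {
   "family": "reduced",
   "params": {
    "p": 0.1
   },
   "target_nd": null
  },
  {
   "family": "reduced",
   "params": {
    "p": 0.2
   },
   "target_nd": null
  },
  {
   "family": "reduced",
   "params": {
    "p": 0.3
   },
   "target_nd": null
  },
  {
   "family": "reduced",
   "params": {
    "p": 0.5
   },
   "target_nd": null
  }
 ]
}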