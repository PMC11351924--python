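{
 "centerline": {
  "coef": [
   2.1737414293277153,
   2.844186088086939
  ],
  "features": [
   "mean_tortuosity",
   "mean_width"
  ],
  "intercept": 0.48482514517072367,
  "mu": [
   1.028815531453627,
   4.760133074606042
  ],
  "n": 200,
  "seed": 2024,
  "sigma": [
   0.03134451009923579,
   1.3464324653797328
  ],
  "source": "centerline",
  "train_accuracy": 1.0
 },
 "raster": {
  "coef": [
   1.405195933138378,
   3.916097029544737
  ],
  "features": [
   "mean_tortuosity",
   "mean_width"
  ],
  "intercept": 0.4345377600904146,
  "mu": [
   1.1052764335737641,
   4.9765555798865115
  ],
  "n": 200,
  "seed": 2024,
  "sigma": [
   0.11442237621085743,
   1.1917265133663115
  ],
  "source": "raster",
  "train_accuracy": 1.0
 }
}
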