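{
 "patch_regions": {
  "1": [
   0.03,
   0.02,
   0.15,
   0.08055
  ],
  "2": [
   0.03,
   0.09385,
   0.15,
   0.1544
  ],
  "3": [
   0.03,
   0.16769,
   0.15,
   0.22825
  ],
  "4": [
   0.03,
   0.24154,
   0.15,
   0.30209
  ],
  "5": [
   0.03,
   0.31538,
   0.15,
   0.37594
  ],
  "6": [
   0.03,
   0.38923,
   0.15,
   0.44978
  ],
  "7": [
   0.03,
   0.46308,
   0.15,
   0.52363
  ],
  "8": [
   0.03,
   0.53692,
   0.15,
   0.59748
  ],
  "9": [
   0.03,
   0.61077,
   0.15,
   0.67132
  ],
  "10": [
   0.03,
   0.68462,
   0.15,
   0.74517
  ],
  "11": [
   0.03,
   0.75846,
   0.15,
   0.81902
  ],
  "12": [
   0.03,
   0.83231,
   0.15,
   0.89286
  ],
  "13": [
   0.03,
   0.90615,
   0.15,
   0.96671
  ],
  "14": [
   0.17,
   0.02,
   0.29,
   0.08055
  ],
  "15": [
   0.17,
   0.09385,
   0.29,
   0.1544
  ],
  "16": [
   0.17,
   0.16769,
   0.29,
   0.22825
  ],
  "17": [
   0.17,
   0.24154,
   0.29,
   0.30209
  ],
  "18": [
   0.17,
   0.31538,
   0.29,
   0.37594
  ],
  "19": [
   0.17,
   0.38923,
   0.29,
   0.44978
  ],
  "20": [
   0.17,
   0.46308,
   0.29,
   0.52363
  ],
  "21": [
   0.17,
   0.53692,
   0.29,
   0.59748
  ],
  "22": [
   0.17,
   0.61077,
   0.29,
   0.67132
  ],
  "23": [
   0.17,
   0.68462,
   0.29,
   0.74517
  ],
  "24": [
   0.17,
   0.75846,
   0.29,
   0.81902
  ],
  "25": [
   0.17,
   0.83231,
   0.29,
   0.89286
  ],
  "26": [
   0.17,
   0.90615,
   0.29,
   0.96671
  ]
 },
 "well_regions": [
  [
   0.36,
   0.18,
   0.48,
   0.32
  ],
  [
   0.52,
   0.18,
   0.64,
   0.32
  ],
  [
   0.36,
   0.42,
   0.48,
   0.56
  ],
  [
   0.52,
   0.42,
   0.64,
   0.56
  ],
  [
   0.36,
   0.66,
   0.48,
   0.8
  ],
  [
   0.52,
   0.66,
   0.64,
   0.8
  ]
 ],
 "card_aspect": 0.6,
 "mirrored_ids": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11,
  12,
  13,
  14,
  15,
  16,
  17,
  18,
  19,
  20,
  21,
  22,
  23,
  24
 ]
}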