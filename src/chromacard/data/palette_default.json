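{
 "patches": [
  {
   "id": 1,
   "name": "dark skin",
   "lab_ref": [
    37.99,
    13.56,
    14.06
   ],
   "role": "chromatic"
  },
  {
   "id": 2,
   "name": "light skin",
   "lab_ref": [
    65.71,
    18.13,
    17.81
   ],
   "role": "chromatic"
  },
  {
   "id": 3,
   "name": "blue sky",
   "lab_ref": [
    49.93,
    -4.88,
    -21.93
   ],
   "role": "chromatic"
  },
  {
   "id": 4,
   "name": "foliage",
   "lab_ref": [
    43.14,
    -13.1,
    21.91
   ],
   "role": "chromatic"
  },
  {
   "id": 5,
   "name": "blue flower",
   "lab_ref": [
    55.11,
    8.84,
    -25.4
   ],
   "role": "chromatic"
  },
  {
   "id": 6,
   "name": "bluish green",
   "lab_ref": [
    70.72,
    -33.4,
    -0.2
   ],
   "role": "chromatic"
  },
  {
   "id": 7,
   "name": "orange",
   "lab_ref": [
    62.66,
    36.07,
    57.1
   ],
   "role": "chromatic"
  },
  {
   "id": 8,
   "name": "purplish blue",
   "lab_ref": [
    40.02,
    10.41,
    -45.96
   ],
   "role": "chromatic"
  },
  {
   "id": 9,
   "name": "moderate red",
   "lab_ref": [
    51.12,
    48.24,
    16.25
   ],
   "role": "chromatic"
  },
  {
   "id": 10,
   "name": "purple",
   "lab_ref": [
    30.33,
    22.98,
    -21.59
   ],
   "role": "chromatic"
  },
  {
   "id": 11,
   "name": "yellow green",
   "lab_ref": [
    72.53,
    -23.71,
    57.26
   ],
   "role": "chromatic"
  },
  {
   "id": 12,
   "name": "orange yellow",
   "lab_ref": [
    71.94,
    19.36,
    67.86
   ],
   "role": "chromatic"
  },
  {
   "id": 13,
   "name": "blue",
   "lab_ref": [
    28.78,
    14.18,
    -50.3
   ],
   "role": "chromatic"
  },
  {
   "id": 14,
   "name": "green",
   "lab_ref": [
    55.26,
    -38.34,
    31.37
   ],
   "role": "chromatic"
  },
  {
   "id": 15,
   "name": "red",
   "lab_ref": [
    42.1,
    53.38,
    28.19
   ],
   "role": "chromatic"
  },
  {
   "id": 16,
   "name": "yellow",
   "lab_ref": [
    81.73,
    4.04,
    79.82
   ],
   "role": "chromatic"
  },
  {
   "id": 17,
   "name": "magenta",
   "lab_ref": [
    51.94,
    49.99,
    -14.57
   ],
   "role": "chromatic"
  },
  {
   "id": 18,
   "name": "cyan",
   "lab_ref": [
    51.04,
    -23.03,
    -23.04
   ],
   "role": "chromatic"
  },
  {
   "id": 19,
   "name": "white 9.5",
   "lab_ref": [
    96.54,
    -0.43,
    1.19
   ],
   "role": "grayscale"
  },
  {
   "id": 20,
   "name": "neutral 8",
   "lab_ref": [
    81.26,
    -0.64,
    -0.34
   ],
   "role": "grayscale"
  },
  {
   "id": 21,
   "name": "neutral 6.5",
   "lab_ref": [
    66.77,
    -0.73,
    -0.5
   ],
   "role": "grayscale"
  },
  {
   "id": 22,
   "name": "neutral 5",
   "lab_ref": [
    50.87,
    -0.15,
    -0.27
   ],
   "role": "grayscale"
  },
  {
   "id": 23,
   "name": "neutral 3.5",
   "lab_ref": [
    35.66,
    -0.42,
    -1.23
   ],
   "role": "grayscale"
  },
  {
   "id": 24,
   "name": "black 2",
   "lab_ref": [
    20.46,
    -0.08,
    -0.97
   ],
   "role": "grayscale"
  },
  {
   "id": 25,
   "name": "black reference",
   "lab_ref": [
    0.0,
    0.0,
    0.0
   ],
   "role": "black_ref"
  },
  {
   "id": 26,
   "name": "white reference",
   "lab_ref": [
    100.0,
    0.0,
    0.0
   ],
   "role": "white_ref"
  }
 ],
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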