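{
 "level": 1,
 "width": 13,
 "height": 7,
 "walls": [
  [
   0,
   0
  ],
  [
   0,
   1
  ],
  [
   0,
   2
  ],
  [
   0,
   3
  ],
  [
   0,
   4
  ],
  [
   0,
   5
  ],
  [
   0,
   6
  ],
  [
   1,
   0
  ],
  [
   1,
   2
  ],
  [
   1,
   6
  ],
  [
   2,
   0
  ],
  [
   2,
   2
  ],
  [
   2,
   4
  ],
  [
   2,
   6
  ],
  [
   3,
   0
  ],
  [
   3,
   2
  ],
  [
   3,
   4
  ],
  [
   3,
   6
  ],
  [
   4,
   0
  ],
  [
   4,
   2
  ],
  [
   4,
   4
  ],
  [
   4,
   6
  ],
  [
   5,
   0
  ],
  [
   5,
   2
  ],
  [
   5,
   4
  ],
  [
   5,
   6
  ],
  [
   6,
   0
  ],
  [
   6,
   2
  ],
  [
   6,
   4
  ],
  [
   6,
   6
  ],
  [
   7,
   0
  ],
  [
   7,
   2
  ],
  [
   7,
   4
  ],
  [
   7,
   6
  ],
  [
   8,
   0
  ],
  [
   8,
   2
  ],
  [
   8,
   4
  ],
  [
   8,
   6
  ],
  [
   9,
   0
  ],
  [
   9,
   2
  ],
  [
   9,
   4
  ],
  [
   9,
   6
  ],
  [
   10,
   0
  ],
  [
   10,
   2
  ],
  [
   10,
   4
  ],
  [
   10,
   6
  ],
  [
   11,
   0
  ],
  [
   11,
   4
  ],
  [
   11,
   6
  ],
  [
   12,
   0
  ],
  [
   12,
   1
  ],
  [
   12,
   2
  ],
  [
   12,
   3
  ],
  [
   12,
   4
  ],
  [
   12,
   5
  ],
  [
   12,
   6
  ]
 ],
 "start": [
  1,
  1
 ],
 "finish": [
  [
   10,
   5
  ],
  [
   11,
   5
  ]
 ],
 "zones": {
  "1": [
   [
    2,
    1
   ],
   [
    3,
    1
   ],
   [
    4,
    1
   ],
   [
    5,
    1
   ],
   [
    6,
    1
   ],
   [
    7,
    1
   ]
  ],
  "2": [
   [
    8,
    1
   ],
   [
    9,
    1
   ],
   [
    10,
    1
   ],
   [
    11,
    1
   ],
   [
    11,
    2
   ],
   [
    11,
    3
   ]
  ],
  "3": [
   [
    5,
    3
   ],
   [
    6,
    3
   ],
   [
    7,
    3
   ],
   [
    8,
    3
   ],
   [
    9,
    3
   ],
   [
    10,
    3
   ]
  ],
  "4": [
   [
    1,
    3
   ],
   [
    1,
    4
   ],
   [
    1,
    5
   ],
   [
    2,
    3
   ],
   [
    3,
    3
   ],
   [
    4,
    3
   ]
  ],
  "5": [
   [
    2,
    5
   ],
   [
    3,
    5
   ],
   [
    4,
    5
   ],
   [
    5,
    5
   ],
   [
    6,
    5
   ],
   [
    7,
    5
   ],
   [
    8,
    5
   ],
   [
    9,
    5
   ],
   [
    10,
    5
   ],
   [
    11,
    5
   ]
  ]
 },
 "checkpoints": [
  2,
  4,
  "F"
 ]
}
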