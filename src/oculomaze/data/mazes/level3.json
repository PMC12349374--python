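{
 "level": 3,
 "width": 19,
 "height": 11,
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
   0,
   7
  ],
  [
   0,
   8
  ],
  [
   0,
   9
  ],
  [
   0,
   10
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
   1,
   10
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
   2,
   8
  ],
  [
   2,
   10
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
   3,
   8
  ],
  [
   3,
   10
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
   4,
   8
  ],
  [
   4,
   10
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
   5,
   8
  ],
  [
   5,
   10
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
   6,
   8
  ],
  [
   6,
   10
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
   7,
   8
  ],
  [
   7,
   10
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
   8,
   8
  ],
  [
   8,
   10
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
   9,
   8
  ],
  [
   9,
   10
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
   10,
   8
  ],
  [
   10,
   10
  ],
  [
   11,
   0
  ],
  [
   11,
   2
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
   11,
   8
  ],
  [
   11,
   10
  ],
  [
   12,
   0
  ],
  [
   12,
   2
  ],
  [
   12,
   4
  ],
  [
   12,
   6
  ],
  [
   12,
   8
  ],
  [
   12,
   10
  ],
  [
   13,
   0
  ],
  [
   13,
   2
  ],
  [
   13,
   4
  ],
  [
   13,
   6
  ],
  [
   13,
   8
  ],
  [
   13,
   10
  ],
  [
   14,
   0
  ],
  [
   14,
   2
  ],
  [
   14,
   4
  ],
  [
   14,
   6
  ],
  [
   14,
   8
  ],
  [
   14,
   10
  ],
  [
   15,
   0
  ],
  [
   15,
   2
  ],
  [
   15,
   4
  ],
  [
   15,
   6
  ],
  [
   15,
   8
  ],
  [
   15,
   10
  ],
  [
   16,
   0
  ],
  [
   16,
   2
  ],
  [
   16,
   4
  ],
  [
   16,
   6
  ],
  [
   16,
   8
  ],
  [
   16,
   10
  ],
  [
   17,
   0
  ],
  [
   17,
   4
  ],
  [
   17,
   8
  ],
  [
   17,
   10
  ],
  [
   18,
   0
  ],
  [
   18,
   1
  ],
  [
   18,
   2
  ],
  [
   18,
   3
  ],
  [
   18,
   4
  ],
  [
   18,
   5
  ],
  [
   18,
   6
  ],
  [
   18,
   7
  ],
  [
   18,
   8
  ],
  [
   18,
   9
  ],
  [
   18,
   10
  ]
 ],
 "start": [
  1,
  1
 ],
 "finish": [
  [
   16,
   9
  ],
  [
   17,
   9
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
   ],
   [
    8,
    1
   ]
  ],
  "2": [
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
    12,
    1
   ],
   [
    13,
    1
   ],
   [
    14,
    1
   ],
   [
    15,
    1
   ]
  ],
  "3": [
   [
    14,
    3
   ],
   [
    15,
    3
   ],
   [
    16,
    1
   ],
   [
    16,
    3
   ],
   [
    17,
    1
   ],
   [
    17,
    2
   ],
   [
    17,
    3
   ]
  ],
  "4": [
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
   ],
   [
    11,
    3
   ],
   [
    12,
    3
   ],
   [
    13,
    3
   ]
  ],
  "5": [
   [
    1,
    3
   ],
   [
    1,
    4
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
   ],
   [
    5,
    3
   ],
   [
    6,
    3
   ]
  ],
  "6": [
   [
    1,
    5
   ],
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
   ]
  ],
  "7": [
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
   ],
   [
    12,
    5
   ],
   [
    13,
    5
   ],
   [
    14,
    5
   ]
  ],
  "8": [
   [
    15,
    5
   ],
   [
    15,
    7
   ],
   [
    16,
    5
   ],
   [
    16,
    7
   ],
   [
    17,
    5
   ],
   [
    17,
    6
   ],
   [
    17,
    7
   ]
  ],
  "9": [
   [
    8,
    7
   ],
   [
    9,
    7
   ],
   [
    10,
    7
   ],
   [
    11,
    7
   ],
   [
    12,
    7
   ],
   [
    13,
    7
   ],
   [
    14,
    7
   ]
  ],
  "10": [
   [
    1,
    7
   ],
   [
    2,
    7
   ],
   [
    3,
    7
   ],
   [
    4,
    7
   ],
   [
    5,
    7
   ],
   [
    6,
    7
   ],
   [
    7,
    7
   ]
  ],
  "11": [
   [
    1,
    8
   ],
   [
    1,
    9
   ],
   [
    2,
    9
   ],
   [
    3,
    9
   ],
   [
    4,
    9
   ],
   [
    5,
    9
   ],
   [
    6,
    9
   ]
  ],
  "12": [
   [
    7,
    9
   ],
   [
    8,
    9
   ],
   [
    9,
    9
   ],
   [
    10,
    9
   ],
   [
    11,
    9
   ],
   [
    12,
    9
   ],
   [
    13,
    9
   ],
   [
    14,
    9
   ],
   [
    15,
    9
   ],
   [
    16,
    9
   ],
   [
    17,
    9
   ]
  ]
 },
 "checkpoints": [
  6,
  11,
  "F"
 ]
}
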