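{
 "n": 9,
 "p": 0.01,
 "q": 1.0,
 "r": [
  0.5,
  0.5
 ],
 "contexts": [
  {
   "predictors": [
    [],
    [],
    [
     2,
     5,
     9
    ],
    [
     2,
     3
    ],
    [
     2,
     3,
     5,
     6,
     7,
     8
    ],
    [
     9
    ],
    [
     5,
     6,
     9
    ],
    [
     5,
     6,
     7,
     8,
     9
    ],
    [
     6,
     7
    ]
   ],
   "truth_tables": [
    [
     1
    ],
    [
     0
    ],
    [
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0
    ],
    [
     0,
     1,
     0,
     0
    ],
    [
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0
    ],
    [
     0,
     1
    ],
    [
     1,
     0,
     1,
     1,
     0,
     0,
     1,
     1
    ],
    [
     1,
     1,
     1,
     1,
     0,
     0,
     0,
     1,
     1,
     1,
     1,
     1,
     0,
     0,
     1,
     1,
     1,
     1,
     1,
     1,
     0,
     0,
     1,
     1,
     1,
     1,
     1,
     1,
     0,
     0,
     1,
     1
    ],
    [
     1,
     0,
     0,
     0
    ]
   ]
  },
  {
   "predictors": [
    [],
    [
     4,
     5,
     9
    ],
    [
     2,
     5,
     9
    ],
    [
     2,
     3
    ],
    [
     2,
     3,
     5,
     6,
     7,
     8
    ],
    [
     9
    ],
    [
     5,
     6,
     9
    ],
    [
     5,
     6,
     7,
     8,
     9
    ],
    [
     6,
     7
    ]
   ],
   "truth_tables": [
    [
     0
    ],
    [
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0
    ],
    [
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0
    ],
    [
     0,
     1,
     0,
     0
    ],
    [
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0,
     0
    ],
    [
     0,
     1
    ],
    [
     1,
     0,
     1,
     1,
     0,
     0,
     1,
     1
    ],
    [
     1,
     1,
     1,
     1,
     0,
     0,
     0,
     1,
     1,
     1,
     1,
     1,
     0,
     0,
     1,
     1,
     1,
     1,
     1,
     1,
     0,
     0,
     1,
     1,
     1,
     1,
     1,
     1,
     0,
     0,
     1,
     1
    ],
    [
     1,
     0,
     0,
     0
    ]
   ]
  }
 ],
 "gene_names": [
  "CycD",
  "Rb",
  "E2F",
  "CycE",
  "CycA",
  "Cdc20",
  "Cdh1",
  "UbcH10",
  "CycB"
 ]
}
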