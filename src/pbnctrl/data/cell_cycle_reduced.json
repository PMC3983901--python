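{
 "n": 5,
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
     3,
     4,
     5
    ],
    [
     3,
     4,
     5
    ],
    [
     3,
     5
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
     1,
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
     0
    ],
    [
     0,
     0,
     0,
     1,
     1,
     0,
     1,
     1
    ],
    [
     0,
     0,
     1,
     0
    ]
   ]
  },
  {
   "predictors": [
    [],
    [
     2,
     3,
     5
    ],
    [
     2,
     3,
     4,
     5
    ],
    [
     3,
     4,
     5
    ],
    [
     3,
     5
    ]
   ],
   "truth_tables": [
    [
     0
    ],
    [
     0,
     0,
     0,
     0,
     1,
     0,
     0,
     0
    ],
    [
     1,
     0,
     0,
     0,
     1,
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
     0
    ],
    [
     0,
     0,
     0,
     1,
     1,
     0,
     1,
     1
    ],
    [
     0,
     0,
     1,
     0
    ]
   ]
  }
 ],
 "gene_names": [
  "CycD",
  "Rb",
  "CycA",
  "UbcH10",
  "CycB"
 ]
}
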