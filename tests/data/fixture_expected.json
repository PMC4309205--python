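{
 "constant": {
  "attractors": [
   {
    "inputs": [],
    "size": 1,
    "stable": true
   }
  ],
  "interaction_signs": {},
  "stable_full_states": [
   [
    0
   ]
  ]
 },
 "negative_circuit": {
  "attractors": [
   {
    "inputs": [],
    "size": 4,
    "stable": false
   }
  ],
  "interaction_signs": {
   "A->B": "activation",
   "B->A": "inhibition"
  },
  "stable_full_states": []
 },
 "self_activator": {
  "attractors": [
   {
    "inputs": [],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [],
    "size": 1,
    "stable": true
   }
  ],
  "interaction_signs": {
   "C->C": "activation"
  },
  "stable_full_states": [
   [
    0
   ],
   [
    1
   ]
  ]
 },
 "step": {
  "attractors": [
   {
    "inputs": [
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1
    ],
    "size": 1,
    "stable": true
   }
  ],
  "interaction_signs": {
   "J->M": "activation"
  },
  "stable_full_states": [
   [
    0,
    0
   ],
   [
    1,
    2
   ]
  ]
 },
 "th_demo": {
  "attractors": [
   {
    "inputs": [
     0,
     0,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     0,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     0,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     0,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     0,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     0,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     1,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     1,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     1,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     1,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     1,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     0,
     1,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     0,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     0,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     0,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     0,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     0,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     1,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     1,
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     1,
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1,
     1,
     1
    ],
    "size": 1,
    "stable": true
   }
  ],
  "interaction_signs": {
   "APC->Stat4": "activation",
   "APC->Stat6": "activation",
   "Gata3->Gata3": "activation",
   "Gata3->IL4": "activation",
   "Gata3->Stat4": "inhibition",
   "Gata3->Tbet": "inhibition",
   "IFNG->Stat1": "activation",
   "IL12_e->Stat4": "activation",
   "IL4->Stat6": "activation",
   "IL4_e->Stat6": "activation",
   "Stat1->IL4": "inhibition",
   "Stat1->Tbet": "activation",
   "Stat4->IFNG": "activation",
   "Stat6->Gata3": "activation",
   "Tbet->Gata3": "inhibition",
   "Tbet->IFNG": "activation",
   "Tbet->Tbet": "activation"
  },
  "stable_full_states": [
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
    1,
    0,
    1
   ],
   [
    0,
    0,
    0,
    1,
    0,
    0,
    1,
    0,
    1,
    0
   ],
   [
    0,
    0,
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
    0,
    1,
    0,
    0,
    0,
    0,
    1,
    0,
    1
   ],
   [
    0,
    0,
    1,
    1,
    0,
    0,
    1,
    0,
    1,
    0
   ],
   [
    0,
    1,
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
    1,
    0,
    0,
    0,
    0,
    0,
    1,
    0,
    1
   ],
   [
    0,
    1,
    0,
    1,
    0,
    0,
    1,
    0,
    1,
    0
   ],
   [
    0,
    1,
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
    1,
    0,
    0,
    0,
    0,
    1,
    0,
    1
   ],
   [
    0,
    1,
    1,
    1,
    0,
    0,
    1,
    0,
    1,
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
    1,
    0,
    1,
    0,
    1
   ],
   [
    1,
    0,
    0,
    1,
    0,
    0,
    1,
    0,
    1,
    0
   ],
   [
    1,
    0,
    1,
    0,
    0,
    1,
    0,
    1,
    0,
    1
   ],
   [
    1,
    0,
    1,
    1,
    0,
    1,
    1,
    0,
    1,
    0
   ],
   [
    1,
    1,
    0,
    0,
    0,
    1,
    0,
    1,
    0,
    1
   ],
   [
    1,
    1,
    0,
    1,
    1,
    0,
    1,
    0,
    1,
    0
   ],
   [
    1,
    1,
    1,
    0,
    0,
    1,
    0,
    1,
    0,
    1
   ],
   [
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    0,
    1,
    0
   ]
  ]
 },
 "toggle": {
  "attractors": [
   {
    "inputs": [
     0
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1
    ],
    "size": 1,
    "stable": true
   },
   {
    "inputs": [
     1
    ],
    "size": 1,
    "stable": true
   }
  ],
  "interaction_signs": {
   "A->B": "inhibition",
   "B->A": "inhibition",
   "I->A": "activation"
  },
  "stable_full_states": [
   [
    0,
    0,
    1
   ],
   [
    1,
    0,
    1
   ],
   [
    1,
    1,
    0
   ]
  ]
 }
}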