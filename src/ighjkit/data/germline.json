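{
 "consensus": {
  "j_nonamer": "CCAAAAACA",
  "heptamer": "CACAGTG",
  "d_nonamer": "ACAAAAACC",
  "nominal_spacer_j": 23,
  "nominal_spacer_d": 12,
  "j_nonamer_alternate": "CCAAAAAAA"
 },
 "ighj": [
  {
   "name": "IGHJ1",
   "coding_length_aa": 17,
   "spacer_length": 22,
   "nonamer_mutations": [
    {
     "position": 4,
     "frm": "A",
     "to": "G"
    }
   ],
   "heptamer_mutations": [
    {
     "position": 4,
     "frm": "A",
     "to": "G"
    }
   ],
   "discrepancies": []
  },
  {
   "name": "IGHJ2",
   "coding_length_aa": 17,
   "spacer_length": 22,
   "nonamer_mutations": [
    {
     "position": 9,
     "frm": "A",
     "to": "T",
     "printed": "9-9 C>A",
     "consistent": false
    }
   ],
   "heptamer_mutations": [
    {
     "position": 6,
     "frm": "T",
     "to": "C"
    },
    {
     "position": 7,
     "frm": "G",
     "to": "C"
    }
   ],
   "discrepancies": [
    "nonamer substitution printed as position 9 C>A; C matches neither strand at position 9, so the printed letters are interpreted on the GGTTTTTGT strand (T>A there, A>T on the stored CCAAAAACA strand)"
   ]
  },
  {
   "name": "IGHJ3",
   "coding_length_aa": 16,
   "spacer_length": 23,
   "nonamer_mutations": [
    {
     "position": 4,
     "frm": "A",
     "to": "C"
    }
   ],
   "heptamer_mutations": [
    {
     "position": 6,
     "frm": "T",
     "to": "G"
    }
   ],
   "discrepancies": []
  },
  {
   "name": "IGHJ4",
   "coding_length_aa": 15,
   "spacer_length": 23,
   "nonamer_mutations": [],
   "heptamer_mutations": [
    {
     "position": 5,
     "frm": "G",
     "to": "T"
    }
   ],
   "discrepancies": [
    "heptamer also printed literally as CAATGTG (two substitutions vs consensus); single positional substitution 7-5 G>T retained",
    "coding length also described as 16 aa; 15 aa retained from the enumerated list"
   ]
  },
  {
   "name": "IGHJ5",
   "coding_length_aa": 16,
   "spacer_length": 22,
   "spacer_length_alternates": [
    21
   ],
   "nonamer_mutations": [
    {
     "position": 6,
     "frm": "A",
     "to": "G"
    },
    {
     "position": 8,
     "frm": "C",
     "to": "A"
    }
   ],
   "heptamer_mutations": [
    {
     "position": 5,
     "frm": "G",
     "to": "T"
    }
   ],
   "discrepancies": [
    "heptamer also printed literally as CAATGTG; positional substitution retained",
    "spacer length reported as 21 or 22 bp; 22 retained, 21 kept as alternate"
   ]
  },
  {
   "name": "IGHJ6",
   "coding_length_aa": 20,
   "spacer_length": 22,
   "nonamer_mutations": [],
   "heptamer_mutations": [
    {
     "position": 5,
     "frm": "G",
     "to": "A"
    }
   ],
   "discrepancies": [
    "heptamer substitution also described as 7-3 C>T; 7-5 G>A retained"
   ]
  }
 ],
 "ighd": [
  {
   "name": "IGHD1-1",
   "coding_length_nt": 17,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD1-7",
   "coding_length_nt": 17,
   "pairing_tier": "low"
  },
  {
   "name": "IGHD1-14",
   "coding_length_nt": 17,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD1-20",
   "coding_length_nt": 17,
   "pairing_tier": "low"
  },
  {
   "name": "IGHD1-26",
   "coding_length_nt": 17,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD2-2",
   "coding_length_nt": 31,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD2-8",
   "coding_length_nt": 31,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD2-15",
   "coding_length_nt": 31,
   "pairing_tier": "high"
  },
  {
   "name": "IGHD2-21",
   "coding_length_nt": 31,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD3-3",
   "coding_length_nt": 31,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD3-9",
   "coding_length_nt": 31,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD3-10",
   "coding_length_nt": 31,
   "pairing_tier": "high"
  },
  {
   "name": "IGHD3-16",
   "coding_length_nt": 31,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD3-22",
   "coding_length_nt": 31,
   "pairing_tier": "high"
  },
  {
   "name": "IGHD4-4",
   "coding_length_nt": 16,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD4-11",
   "coding_length_nt": 16,
   "pairing_tier": "low"
  },
  {
   "name": "IGHD4-17",
   "coding_length_nt": 16,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD4-23",
   "coding_length_nt": 16,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD5-5",
   "coding_length_nt": 23,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD5-12",
   "coding_length_nt": 23,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD5-18",
   "coding_length_nt": 23,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD5-24",
   "coding_length_nt": 23,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD6-6",
   "coding_length_nt": 18,
   "pairing_tier": "medium"
  },
  {
   "name": "IGHD6-13",
   "coding_length_nt": 18,
   "pairing_tier": "high"
  },
  {
   "name": "IGHD6-19",
   "coding_length_nt": 18,
   "pairing_tier": "high"
  },
  {
   "name": "IGHD6-25",
   "coding_length_nt": 18,
   "pairing_tier": "low"
  },
  {
   "name": "IGHD7-27",
   "coding_length_nt": 11,
   "pairing_tier": "low"
  }
 ]
}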