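[
  {
    "name": "EGFR_ex18_719",
    "description": "EGFR exon 18, codon 719",
    "target": "DSCTCCGGTGC",
    "wildtype_assignment": {"1": "G", "2": "G"},
    "dispensation_order": "CATGTCACTCGTG",
    "orientation": "forward",
    "variants": [
      {"id": "G719A", "edit": {"type": "substitution", "position": 2, "new": "C"}, "notes": "GGC>GCC"},
      {"id": "G719C", "edit": {"type": "substitution", "position": 1, "new": "T"}, "notes": "GGC>TGC"},
      {"id": "G719S", "edit": {"type": "substitution", "position": 1, "new": "A"}, "notes": "GGC>AGC"}
    ]
  },
  {
    "name": "EGFR_ex19_del",
    "description": "EGFR exon 19 deletions",
    "target": "TATCAA[GGAATTAAGAGAAGC]AACATCTCCGAAAGCCA",
    "wildtype_assignment": {},
    "dispensation_order": "CTATCACTGTCAGCTCGATCGTCATCGTCACGC",
    "orientation": "forward",
    "variants": [
      {"id": "E746_A750del", "edit": {"type": "deletion", "start": 7, "length": 15}, "notes": "c.2235_2249del15; removes the bracketed block"},
      {"id": "E746_A750del_2236", "edit": {"type": "deletion", "start": 8, "length": 15}, "notes": "c.2236_2250del15"},
      {"id": "L747_E749del", "edit": {"type": "deletion", "start": 11, "length": 9}, "notes": "c.2239_2247del9"},
      {"id": "L747_T751del", "edit": {"type": "deletion", "start": 12, "length": 15}, "notes": "c.2240_2254del15"},
      {"id": "L747_S752del", "edit": {"type": "deletion", "start": 11, "length": 18}, "notes": "c.2239_2256del18"},
      {"id": "E746_T751del", "edit": {"type": "deletion", "start": 9, "length": 15}, "notes": "c.2237_2251del15 (E746_T751delinsA)"},
      {"id": "L747_P753delinsS", "edit": {"type": "delins", "start": 12, "length": 18, "replacement": "T"}, "notes": "c.2240_2257delinsT"},
      {"id": "L747_A750delinsP", "edit": {"type": "delins", "start": 11, "length": 10, "replacement": "C"}, "notes": "c.2239_2248delinsC"},
      {"id": "L747_T751delinsP", "edit": {"type": "delins", "start": 11, "length": 13, "replacement": "C"}, "notes": "c.2239_2251delinsC"},
      {"id": "E746_S752delinsV", "edit": {"type": "delins", "start": 9, "length": 19, "replacement": "T"}, "notes": "c.2237_2255delinsT"}
    ]
  },
  {
    "name": "EGFR_ex20_768",
    "description": "EGFR exon 20, Codon 768 and insertions",
    "target": "CAGCGTGGACAACCCCCACG",
    "wildtype_assignment": {},
    "dispensation_order": "GCAGTACGTGTCGTGTACGTGACCACACTG",
    "orientation": "forward",
    "variants": [
      {"id": "S768I", "edit": {"type": "substitution", "position": 3, "new": "T"}, "notes": "AGC>ATC, c.2303G>T"},
      {"id": "V769_D770insASV", "edit": {"type": "insertion", "after": 7, "bases": "GCCAGCGTG"}, "notes": "9-bp in-frame insertion"},
      {"id": "D770_N771insG", "edit": {"type": "insertion", "after": 10, "bases": "GGT"}, "notes": "3-bp in-frame insertion"},
      {"id": "H773_V774insH", "edit": {"type": "insertion", "after": 19, "bases": "CAC"}, "notes": "3-bp in-frame insertion"}
    ]
  },
  {
    "name": "EGFR_ex20_T790",
    "description": "EGFR exon 20, Codon 790",
    "target": "ATCAYG",
    "wildtype_assignment": {"5": "C"},
    "dispensation_order": "GATTCATCTG",
    "orientation": "forward",
    "variants": [
      {"id": "T790M", "edit": {"type": "substitution", "position": 5, "new": "T"}, "notes": "ACG>ATG, c.2369C>T"}
    ]
  },
  {
    "name": "EGFR_ex21",
    "description": "EGFR exon 21",
    "target": "CKGGCCAAACDGCTGGGT",
    "wildtype_assignment": {"2": "T", "11": "T"},
    "dispensation_order": "ACGTGTCACATGTC",
    "orientation": "forward",
    "reference_positions": [2, 9, 11, 12, 14],
    "variants": [
      {"id": "L858R", "edit": {"type": "substitution", "position": 2, "new": "G"}, "notes": "T>G; mutant G run at dispensation 3"},
      {"id": "L861Q", "edit": {"type": "substitution", "position": 11, "new": "A"}, "notes": "CTG>CAG"}
    ]
  },
  {
    "name": "KRAS_12_13",
    "description": "KRAS codon 12 & 13",
    "target": "NNTGRCGTAGGC",
    "wildtype_assignment": {"1": "G", "2": "G", "5": "G"},
    "dispensation_order": "ACTGTACGTGATCGTAGCAAGAG",
    "orientation": "forward",
    "variants": [
      {"id": "G12A", "edit": {"type": "substitution", "position": 2, "new": "C"}, "notes": "GGT>GCT"},
      {"id": "G12C", "edit": {"type": "substitution", "position": 1, "new": "T"}, "notes": "GGT>TGT"},
      {"id": "G12D", "edit": {"type": "substitution", "position": 2, "new": "A"}, "notes": "GGT>GAT"},
      {"id": "G12R", "edit": {"type": "substitution", "position": 1, "new": "C"}, "notes": "GGT>CGT"},
      {"id": "G12S", "edit": {"type": "substitution", "position": 1, "new": "A"}, "notes": "GGT>AGT"},
      {"id": "G12V", "edit": {"type": "substitution", "position": 2, "new": "T"}, "notes": "GGT>GTT"},
      {"id": "G13D", "edit": {"type": "substitution", "position": 5, "new": "A"}, "notes": "GGC>GAC"}
    ]
  },
  {
    "name": "KRAS_61",
    "description": "KRAS codon 61 (reverse sequencing)",
    "target": "CTCDTGACCTG",
    "wildtype_assignment": {"4": "T"},
    "dispensation_order": "GCTCGATACGACCT",
    "orientation": "reverse",
    "variants": [
      {"id": "Q61H", "edit": {"type": "substitution", "position": 4, "new": "G"}, "notes": "CAA>CAC (sense), c.183A>C"},
      {"id": "Q61K", "edit": {"type": "substitution", "position": 6, "new": "T"}, "notes": "CAA>AAA (sense)"},
      {"id": "Q61L", "edit": {"type": "substitution", "position": 5, "new": "A"}, "notes": "CAA>CTA (sense)"},
      {"id": "Q61P", "edit": {"type": "substitution", "position": 5, "new": "G"}, "notes": "CAA>CCA (sense)"},
      {"id": "Q61R", "edit": {"type": "substitution", "position": 5, "new": "C"}, "notes": "CAA>CGA (sense)"}
    ]
  },
  {
    "name": "BRAF_600",
    "description": "BRAF codon 600 (reverse sequencing)",
    "target": "CWCTGTAG",
    "wildtype_assignment": {"2": "A"},
    "dispensation_order": "TCGTATCTGTAG",
    "orientation": "reverse",
    "reference_positions": [9, 10, 12],
    "unexpected_positions": [1, 3, 6],
    "variants": [
      {"id": "V600E", "edit": {"type": "substitution", "position": 2, "new": "T"}, "notes": "GTG>GAG (sense); read CACTGTAG>CTCTGTAG"},
      {"id": "V600K", "edit": {"type": "substitution", "position": 2, "new": "TT"}, "notes": "GTG>AAG (sense); read CACTGTAG>CTTTGTAG"},
      {"id": "V600R", "edit": {"type": "substitution", "position": 2, "new": "CT"}, "notes": "GTG>AGG (sense); read CACTGTAG>CCTTGTAG"}
    ]
  }
]
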