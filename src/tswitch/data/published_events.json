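{
  "description": "Published parental/derived sequence pairs for the ten spacer-inversion events in S. cerevisiae coding genes (spacer lowercase, as published). frame_offset anchors the reading frame of each excerpt, recovered by locating the reported codons inside the sequences. replacements lists the reported per-codon changes (synonymous ones included).",
  "events": [
    {
      "gene": "PIM1",
      "arm_len": 10,
      "spacer_len": 3,
      "strains": ["YJM339"],
      "parental": "CTCCAGAAGCtccGCTTCTGGAG",
      "derived": "CTCCAGAAGCggaGCTTCTGGAG",
      "frame_offset": 1,
      "replacements": [
        {"from_aa": "S", "to_aa": "G", "from_codon": "TCC", "to_codon": "GGA"}
      ]
    },
    {
      "gene": "REG2",
      "arm_len": 16,
      "spacer_len": 5,
      "strains": ["YJM339"],
      "parental": "ACAGCGCCCTTGTTCAaagtcTGAACTAGATCCCTGT",
      "derived": "ACAGCGCCCTTGTTCAgacttTGAACAAGGGCGCTGT",
      "frame_offset": 1,
      "replacements": [
        {"from_aa": "K", "to_aa": "D", "from_codon": "AAG", "to_codon": "GAC"},
        {"from_aa": "S", "to_aa": "F", "from_codon": "TCT", "to_codon": "TTT"}
      ]
    },
    {
      "gene": "SYG1",
      "arm_len": 10,
      "spacer_len": 4,
      "strains": ["JAY291"],
      "parental": "ATCCAGCTCCtaccGGAGCTGGAT",
      "derived": "ATCCAGCTCCggtaGGAGCTGGAT",
      "frame_offset": 1,
      "replacements": [
        {"from_aa": "Y", "to_aa": "G", "from_codon": "TAC", "to_codon": "GGT"},
        {"from_aa": "R", "to_aa": "R", "from_codon": "CGG", "to_codon": "AGG"}
      ]
    },
    {
      "gene": "AYR1",
      "arm_len": 10,
      "spacer_len": 4,
      "strains": ["UWOPS05_217_3", "YJM269"],
      "parental": "CTAATTTACCtgatGGTAAATTAG",
      "derived": "CTAATTTACCatcaGGTAAATTAG",
      "frame_offset": 2,
      "replacements": [
        {"from_aa": "P", "to_aa": "P", "from_codon": "CCT", "to_codon": "CCA"},
        {"from_aa": "D", "to_aa": "S", "from_codon": "GAT", "to_codon": "TCA"}
      ]
    },
    {
      "gene": "SPO75",
      "arm_len": 11,
      "spacer_len": 2,
      "strains": ["D273-10B", "CEN.PK", "Y55"],
      "parental": "TGCCCGACGATttATCGTCGGGCA",
      "derived": "TGCCCGACGATaaATCGTCGGGCA",
      "frame_offset": 2,
      "replacements": [
        {"from_aa": "L", "to_aa": "K", "from_codon": "TTA", "to_codon": "AAA"}
      ]
    },
    {
      "gene": "ICT1",
      "arm_len": 10,
      "spacer_len": 2,
      "strains": ["D273-10B", "SEY6210", "YJM789"],
      "parental": "TGCAGGGCCTgaAGGCCCTGCA",
      "derived": "TGCAGGGCCTtcAGGCCCTGCA",
      "frame_offset": 2,
      "replacements": [
        {"from_aa": "L", "to_aa": "L", "from_codon": "CTG", "to_codon": "CTT"},
        {"from_aa": "K", "to_aa": "Q", "from_codon": "AAG", "to_codon": "CAG"}
      ]
    },
    {
      "gene": "YPS1",
      "arm_len": 11,
      "spacer_len": 3,
      "strains": ["UWOPS05_217_3"],
      "parental": "CCATACTGTTCttcGAACAGTATGG",
      "derived": "CCATACTGTTCgaaGAACAGTATGG",
      "frame_offset": 0,
      "replacements": [
        {"from_aa": "S", "to_aa": "S", "from_codon": "TCT", "to_codon": "TCG"},
        {"from_aa": "S", "to_aa": "K", "from_codon": "TCG", "to_codon": "AAG"}
      ]
    },
    {
      "gene": "ECM30",
      "arm_len": 10,
      "spacer_len": 2,
      "strains": ["W303"],
      "parental": "GGAGGACGCAgaTGCGTCCTCC",
      "derived": "GGAGGACGCAtcTGCGTCCTCC",
      "frame_offset": 1,
      "replacements": [
        {"from_aa": "D", "to_aa": "S", "from_codon": "GAT", "to_codon": "TCT"}
      ]
    },
    {
      "gene": "YBZ1",
      "arm_len": 10,
      "spacer_len": 3,
      "strains": ["Kyokai7", "RedStar", "CLIB215", "L1528"],
      "parental": "TGTCAATGCCttcGGCATTGACA",
      "derived": "TGTCAATGCCgaaGGCATTGACA",
      "frame_offset": 1,
      "replacements": [
        {"from_aa": "F", "to_aa": "E", "from_codon": "TTC", "to_codon": "GAA"}
      ]
    },
    {
      "gene": "TAT2",
      "arm_len": 11,
      "spacer_len": 3,
      "strains": ["SEY6210"],
      "parental": "TTGGATTTGTAgaaTACAAATCCAA",
      "derived": "TTGGATTTGTAttcTACAAATCCAA",
      "frame_offset": 2,
      "replacements": [
        {"from_aa": "E", "to_aa": "F", "from_codon": "GAA", "to_codon": "TTC"}
      ]
    }
  ]
}
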