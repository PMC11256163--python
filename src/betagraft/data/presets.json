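{
  "source": "Published stacked-graft vaccine-candidate designs on the HET-s(218-289) beta-solenoid scaffold (PDB 2RNM); donor surface epitopes from alpha-synuclein fibril structures solved by ssNMR (PDB 2N0A) and cryo-EM (PDB 6H6B). Substitution lists stored verbatim as printed, rung labels included.",
  "scaffold_id": "HET-s(218-289)",
  "rung_offset": 36,
  "entries": {
    "alpha-SC3": {
      "donor_id": "2N0A",
      "donor_method": "ssNMR",
      "rung1": ["K229Q", "D230V", "R232N", "E234G", "E235G"],
      "rung2": ["E265Q", "T266V", "V268N", "K269G"],
      "note": "rung-2 entry K269G stored verbatim; it does not sit at any rung-1 partner + offset and is flagged by validation rather than corrected"
    },
    "alpha-SC6": {
      "donor_id": "6H6B",
      "donor_method": "cryo-EM",
      "rung1": ["R232K", "E234V", "R236G"],
      "rung2": ["V268K", "K270V", "G271E", "E272G"],
      "note": "rung-2-only G271E arises from identity-dropping: the rung-1 partner site 235 already carries the donor letter E"
    },
    "alpha-SC8": {
      "donor_id": "unknown",
      "donor_method": "unknown",
      "rung1": ["R225K", "S227Q", "K229T"],
      "rung2": ["T261K", "S263Q", "E265T"],
      "note": ""
    },
    "alpha-SC9": {
      "donor_id": "unknown",
      "donor_method": "unknown",
      "rung1": ["S227K", "K229V", "D230E", "R232A"],
      "rung2": ["S263K", "E265V", "T266E", "V268A"],
      "note": ""
    }
  }
}
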