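# betagraft

Structure-based epitope grafting onto beta-solenoid scaffolds.

## The problem

Vaccines against synucleinopathies (Parkinson's disease, dementia with Lewy
bodies, multiple system atrophy) must raise antibodies that recognize the
*misfolded, fibrillar* form of alpha-synuclein without touching the abundant
native monomer. Linear peptide antigens cannot do this: the pathological
epitopes are conformational, created by the parallel in-register stacking of
identical chains in the amyloid fibril (residue *i* of each molecule sits
~4.8 Å above residue *i* of the next).

One way to present such an epitope safely is to graft it onto an innocuous
carrier with the same cross-beta architecture. The HET-s(218–289) prion
domain of *Podospora anserina* folds into a left-handed beta-solenoid with
two rungs of four beta-strands each, rungs spaced 4.8 ± 0.2 Å — the same
spacing as the alpha-synuclein fibril. Substituting donor surface residues
onto *both* rungs of the solenoid (position *p* on rung 1 and its structural
partner *p + Δ* on rung 2, Δ being the solenoid's internal repeat offset)
makes the assembled scaffold fibril display the donor's stacked, in-register
surface: two donor molecules' worth of epitope per scaffold molecule.

`betagraft` implements this design procedure as a reusable toolkit:

* **structure_io** — PDB/mmCIF reading (via gemmi), selection, sequence
  extraction, FASTA/PDB writing; author numbering everywhere.
* **fibril_geometry** — screw-fit of fibril axis, rise and twist;
  dihedral-based beta-strand segmentation; rung-offset (Δ) detection;
  parallel in-register verification.
* **surface_analysis** — deterministic Shrake–Rupley SASA (golden-spiral
  point set, no RNG), exposure classes, strand face parity, fibril-context
  stacking.
* **graft_design** — epitope extraction, Kabsch superposition scoring, the
  two-rung stacked-graft rule with identity-dropping, design validation.
* **construct_builder** — the four published vaccine candidates (α-SC3,
  α-SC6, α-SC8, α-SC9) as verbatim presets; sequence editing; JSON/TSV/FASTA
  reports.
* **synthetic_fixtures** — deterministic generators for idealized
  beta-solenoids and in-register fibrils with known ground truth, including
  a synthetic HET-s(218–289) model and an alpha-synuclein-like fibril.

## The core rule

Given donor residue *x* assigned to scaffold rung-1 position *p*, the design
emits substitutions at both *p* and *p + Δ*, skipping any edit whose target
letter already equals the scaffold wild type ("identity-dropping"). This one
rule reproduces the published, apparently asymmetric substitution lists —
e.g. α-SC6's rung-2-only G271E exists because rung-1 partner position 235
already carries the donor's glutamate. After applying any design, positions
*p* and *p + Δ* always carry identical letters ("stack mimicry"), so every
rung of the assembled fibril presents the same surface.

## Worked example

```python
from betagraft import (
    make_het_s_scaffold, extract_sequence, detect_rung_offset,
    design_stacked_graft, validate_design, apply_design,
    EpitopePatch, SiteMapping,
)

scaffold = make_het_s_scaffold()          # synthetic two-rung solenoid model
seq = extract_sequence(scaffold, "A")     # KIDAIVGRNS... numbered 218-289
rung_map = detect_rung_offset(scaffold, "A")
print(rung_map.offset)                    # 36

# alpha-SC8: donor residues K, Q, T assigned to rung-1 positions 225/227/229
patch = EpitopePatch(donor_id="asyn-fibril",
                     residues=((225, "K"), (227, "Q"), (229, "T")),
                     source_chain="A")
mapping = SiteMapping(assignments=((225, 225), (227, 227), (229, 229)),
                      rung_map=rung_map)
design = design_stacked_graft(seq, rung_map, patch, mapping, name="alpha-SC8")
print(design.labels)
# ('R225K', 'S227Q', 'K229T', 'T261K', 'S263Q', 'E265T')
print(validate_design(design, seq, rung_map).clean)   # True
mutant = apply_design(seq, design)        # 72 residues, 6 changed
```

The three rung-1 edits at 225/227/229 reappear automatically at 261/263/265
(Δ = 36). The same can be run from the shell:

```bash
betagraft preset --name alpha-SC9 --out-dir out/
# alpha-SC9: 8 substitutions; validation clean
betagraft analyze --structure my_fibril.pdb --repeat inter-chain --chains A,B,C
```

`betagraft preset --name alpha-SC3` reports validation flags: the published
α-SC3 list contains the rung-2 entry K269G, which matches neither the
scaffold letter at 269 (G) nor any rung-1 partner under Δ = 36; the
stack-mimicry rule instead predicts K270G. The preset stores the printed
list verbatim and the validator surfaces the conflict.

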