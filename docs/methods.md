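# Methods

## The design model

The package treats immunogen design as a geometric grafting problem between
two cross-beta architectures:

* the **donor**: a parallel in-register amyloid fibril (here alpha-synuclein),
  in which identical chains stack along the fibril axis with an axial rise of
  ~4.8 Å, so residue *i* of every molecule is aligned above residue *i* of the
  next, and each strand's side chains alternate between the two sheet faces;
* the **scaffold**: a two-rung beta-solenoid (here the HET-s prion domain,
  residues 218–289), whose one chain winds twice around the axis; rungs are
  related by an internal pseudo-repeat — position *p* on rung 1 corresponds
  structurally to position *p + Δ* on rung 2 — and successive molecules of
  the assembled scaffold fibril stack with the same ~4.8 Å spacing.

Because one scaffold molecule contributes two rungs, placing donor residue
*x* at both *p* and *p + Δ* makes the scaffold fibril display the same
stacked pair of surface residues that two consecutive donor molecules would
display. This is the entire design rule; the package adds the bookkeeping
that makes it reproducible:

1. **Identity-dropping.** An edit whose target letter equals the scaffold
   wild type is skipped and counted, not emitted. Printed substitution lists
   are therefore asymmetric whenever one rung already carries the donor
   letter, and a validator must reason about what is *absent*: a missing
   partner substitution is acceptable exactly when the partner's wild type
   equals the donor letter.
2. **Mapping direction.** Donor residues are assigned to rung-1 positions
   only; rung-2 edits are always derived through Δ. Specifying rung 2
   independently could silently break stack mimicry.
3. **Validation is report-only.** Designs — including the published ones
   stored as presets — are never corrected. The α-SC3 preset carries the
   printed entry K269G, which conflicts with the scaffold letter at 269 and
   has no rung-1 partner under Δ; regeneration from the donor assignments
   yields K270G instead, and both facts are reported, not resolved.

## Geometry measurements

**Helical frame.** Corresponding Cα sets of successive repeats (chains of a
fibril, or the two rung intervals of a solenoid chain) are superposed by
proper-rotation least squares (Kabsch, via scipy's `align_vectors`); the
transform is decomposed into a screw: rotation axis, twist = rotation angle,
rise = translation component along the axis. Multiple repeat pairs are
averaged. For a near-pure translation (twist below ~0.5°) the rotation axis
is undefined and the translation direction is used.

**Strand segmentation** uses backbone dihedrals: a residue is strand-like
when φ ∈ [−180°, −45°] and ψ (mod 360°) ∈ [45°, 225°]; chain termini with
only one defined angle are judged by that angle. Runs of at least
`min_strand_len` (default 3) residues become segments. A dihedral criterion
was chosen over hydrogen-bond (DSSP-style) assignment because it works on
backbone-only models, needs no hydrogen inference, and is deterministic; the
thresholds are exposed as module constants.

**Rung offset.** Δ is the argmin over candidate offsets of the Cα
superposition RMSD between positions {i} and {i+Δ} over the maximal
overlapping window, requiring at least 15 aligned pairs and RMSD ≤ 3.0 Å
(the solenoid pseudo-repeat is approximate in real structures); ties break
toward the smaller Δ. An exhaustive scan is cheap at protein-domain sizes
and avoids any local-minimum concern.

**Register check.** For every residue shared by successive chains, the Cα
displacement vector is compared with the ideal rise translation along the
fitted axis; the reported per-residue offset is the magnitude of the full
3-D deviation, not only its axial component. This matters: a sheet whose
chains are sequence-shifted out of register moves residues *laterally*
(along the chain direction) while leaving axial spacing intact, so an
axial-only criterion cannot detect it. In the degenerate pure-translation
case the axis is additionally re-anchored orthogonal to the chain tangent so
that in-chain slip cannot be absorbed into the fitted axis. The default
tolerance of 2.4 Å (half the canonical rise) separates in-register stacking
from a single-residue shift (Cα–Cα ≈ 3.3–3.8 Å along the chain).

## Solvent accessibility

SASA is Shrake–Rupley with a deterministic golden-spiral point set (default
960 points/atom, probe 1.4 Å) over Bondi-type van der Waals radii frozen in
the module; coordinates are first rotated into a canonical principal-axes
frame so the computed values are exactly invariant under rigid motion of the
input, and bit-stable across runs. Hydrogens are ignored throughout.

Relative SASA divides by per-residue maxima from an extended Gly-X-Gly
tripeptide. Two reference tables exist and must not be mixed: the standard
full-side-chain (Tien-style theoretical) table for experimental structures,
and `backbone_cbeta_reference_maxima()` — computed on the fly from
generator-built Gly-X-Gly tripeptides — for reduced backbone+Cβ models,
which could otherwise never approach the full-atom maxima. Exposure classes
default to exposed ≥ 0.25, buried ≤ 0.05.

**Fibril context.** `stack_repeats` replicates a repeat along its measured
frame (default 5 copies, middle copy scored) because a lone molecule
overstates exposure at the stacking interfaces. Both isolated and stacked
modes are provided; which one the original designers used is not
documented, so neither is hard-wired into the design functions.

**Strand faces.** Side-chain direction is Cα→Cβ (an ideally placed pseudo-Cβ
for glycine) projected perpendicular to the local strand tangent. Because
the beta-pleat tilts all side chains partly the same way, face labels come
from the sign along the *difference* of consecutive projected vectors, which
isolates the two-residue alternation. Residues spaced by two within a strand
therefore share a face, which is the geometric reason the published designs
pick donor positions of equal parity per strand (e.g. 225/227/229).

## Synthetic models and what they do and do not show

All fixtures are generated by pure arithmetic (internal-coordinate chain
building with canonical bond lengths/angles; φ/ψ = −135°/135° strands,
−60°/−30° turns; no RNG anywhere), so rise, twist, offset, register and
sequence are known exactly:

* `make_ideal_solenoid` — rung 0 built from a strand/turn layout, rung *k*
  an exact rotated/translated copy; `make_het_s_scaffold` threads the
  canonical HET-s(218–289) sequence onto a 2×36-residue solenoid
  (rise 4.8 Å, twist −1°, four strands per rung, Δ = 36).
* `make_in_register_fibril` — identical extended chains stacked along the
  axis; options for antiparallel flipping and numbering register shifts;
  `make_synuclein_like_fibril` carries the human alpha-synuclein sequence
  (NAC core 61–95 by default).

These models validate the *analysis machinery* (parameter recovery over a
grid of rises 4.6–5.0 Å and twists −5°…5°, offset detection, register
verdicts, face alternation, the design rule end-to-end against the printed
lists). They are deliberately idealized and differ from experimental
structures in known ways: side chains stop at Cβ; turn conformations are
generic, so consecutive rungs make unphysical contacts in turn regions; and
the flat rung lattice orients strand side chains along the stacking axis
rather than laterally, so *fibril-context exposure classes computed on the
synthetic scaffold do not emulate the real solenoid surface* — exposure
semantics are tested on the isolated fold and on the stacked fibril fixture
instead. Passing tests demonstrate correctness of the measurements and of
the grafting logic, not new structural claims about the real proteins; the
same functions accept experimentally determined PDB/mmCIF files.

## Numerical choices

* Superposition requires ≥ 3 point pairs and always returns det(R) = +1;
  reflections are rejected by construction.
* Screw decomposition flips the axis so rise > 0; twist is reported in
  (−180°, 180°].
* The acceptance script re-runs all analyses after a seeded random rigid
  motion of every input model, demonstrating frame independence; the seed
  feeds only these motions (the pipeline itself contains no randomness).
* Report files are byte-stable: sorted JSON keys, no timestamps; preset
  content is guarded by frozen checksums in the test suite.

## Known limitations

* No side-chain packing, clash scoring or stability prediction: acceptance
  of a graft is geometric (backbone RMSD, exposure, face parity) — the
  original work screened construct stability experimentally, which desk
  analysis cannot replace.
* No automated epitope discovery; donor residues and their scaffold
  assignment are inputs.
* Which donor chains of a multi-chain fibril entry to treat as the reference
  protofilament is a user decision, never guessed.
* The six rejected designs of the original ten are not reproducible from
  published information and are out of scope.
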