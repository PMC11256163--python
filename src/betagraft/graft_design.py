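"""Stacked epitope grafting onto a beta-solenoid scaffold.

The design procedure: take surface residues of a donor parallel in-register
amyloid fibril (two stacked molecules' worth), and substitute them onto
structurally equivalent, surface-exposed positions of *both rungs* of a
two-rung beta-solenoid scaffold.  Because every molecule of the assembled
scaffold fibril carries the same two-rung substitution pattern, the
scaffold's self-stacking then reproduces the donor fibril's in-register
stacking — a conformational epitope, not a linear peptide.

Key rule (identity-dropping): a substitution whose target letter equals the
scaffold wild-type is omitted.  This is what makes printed substitution
lists asymmetric between rungs (e.g. a rung-2-only edit) while stack
mimicry still holds: after applying the design, position ``p`` and its
rung-2 partner ``p + Δ`` always carry the same letter for every mapped site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fibril_geometry import RungMap, StrandSegment, superpose
from .structure_io import AA3_TO_1, SequenceRecord, Structure
from .surface_analysis import ExposureProfile, strand_face_parity

__all__ = [
    "EpitopePatch",
    "SiteMapping",
    "GraftScore",
    "Substitution",
    "ConstructDesign",
    "ValidationReport",
    "extract_epitope",
    "superpose_epitope",
    "design_stacked_graft",
    "validate_design",
]


@dataclass(frozen=True)
class EpitopePatch:
    """An ordered set of donor residues forming a surface epitope."""

    donor_id: str
    residues: tuple[tuple[int, str], ...]  # (author number, one-letter code)
    source_chain: str
    face: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("epitope patch is empty")
        numbers = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("epitope residues must be strictly increasing")
        bad = [c for _, c in self.residues if c not in AA3_TO_1.values()]
        if bad:
            raise ValueError(f"non-standard epitope residue codes: {bad}")

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.residues)

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.residues)


@dataclass(frozen=True)
class SiteMapping:
    """Donor residue -> scaffold rung-1 position assignments.

    Rung-2 positions are never assigned directly; they are always derived
    as ``rung-1 position + Δ`` through the rung map, which is what enforces
    the two-molecules-per-two-rungs stack mimicry.
    """

    assignments: tuple[tuple[int, int], ...]  # (donor number, rung-1 position)
    rung_map: RungMap

    def __post_init__(self) -> None:
        scaffold = [p for _, p in self.assignments]
        if any(b <= a for a, b in zip(scaffold, scaffold[1:])):
            raise ValueError("scaffold positions must be strictly increasing")
        if len(set(scaffold)) != len(scaffold):
            raise ValueError("scaffold positions must be unique")
        lo, hi = self.rung_map.rung1_range
        outside = [p for p in scaffold if not (lo <= p <= hi)]
        if outside:
            raise ValueError(
                f"rung-1 positions {outside} outside rung-1 range {lo}-{hi}"
            )

    @property
    def scaffold_positions(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.assignments)


@dataclass(frozen=True)
class GraftScore:
    """Geometric/exposure acceptance summary for one graft."""

    ca_rmsd: float
    exposure_fraction: float
    parity_consistent: bool
    n_identity_skipped: int = 0

    def __post_init__(self) -> None:
        if self.ca_rmsd < 0:
            raise ValueError("ca_rmsd must be ≥ 0")
        if not (0.0 <= self.exposure_fraction <= 1.0):
            raise ValueError("exposure_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Substitution:
    """One point substitution in author numbering, e.g. K229Q."""

    position: int
    wt: str
    new: str
    rung: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.wt == self.new:
            raise ValueError(f"identity substitution at {self.position}")
        if self.rung not in (1, 2):
            raise ValueError("rung must be 1 or 2")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.new}"

    @classmethod
    def parse(cls, label: str, rung: int) -> "Substitution":
        """Parse a label like ``K229Q`` into a substitution."""
        wt, new = label[0], label[-1]
        return cls(position=int(label[1:-1]), wt=wt, new=new, rung=rung)


@dataclass(frozen=True)
class ConstructDesign:
    """A named substitution set on the scaffold -- one vaccine candidate."""

    name: str
    scaffold_id: str
    substitutions: tuple[Substitution, ...]
    provenance: dict = field(default_factory=dict)
    score: Optional[GraftScore] = None

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be unique")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.substitutions)

    def rung_labels(self, rung: int) -> tuple[str, ...]:
        return tuple(s.label for s in self.substitutions if s.rung == rung)


@dataclass(frozen=True)
class ValidationReport:
    """Report-only validation outcome; the design is never mutated."""

    wt_mismatches: tuple[str, ...] = ()
    asymmetries: tuple[str, ...] = ()
    out_of_range: tuple[str, ...] = ()

    @property
    def clean(self) -> bool:
        return not (self.wt_mismatches or self.asymmetries or self.out_of_range)

    @property
    def flags(self) -> tuple[str, ...]:
        return self.wt_mismatches + self.asymmetries + self.out_of_range


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_epitope(
    donor: Structure,
    chain: str,
    residue_numbers: Sequence[int],
    require_exposed: bool = False,
    profile: Optional[ExposureProfile] = None,
) -> EpitopePatch:
    """Read an epitope patch off a donor fibril structure.

    One-letter codes come from the structure itself.  With
    ``require_exposed`` every residue must classify exposed or intermediate
    in the supplied exposure profile; buried residues abort the extraction.
    """
    from .structure_io import extract_sequence

    seq = extract_sequence(donor, chain)
    residues: list[tuple[int, str]] = []
    for num in residue_numbers:
        try:
            letter = seq.letter_at(num)
        except IndexError as exc:
            raise ValueError(f"residue {num} absent from chain {chain!r}") from exc
        if letter == "X":
            raise ValueError(f"residue {num} is non-standard; cannot graft it")
        residues.append((num, letter))

    if require_exposed:
        if profile is None:
            raise ValueError("require_exposed needs an exposure profile")
        if not profile.classes:
            raise ValueError("exposure profile has no classes; run classify_exposure")
        buried = [
            num
            for num, _ in residues
            if profile.classes.get((chain, num), "missing") == "buried"
        ]
        if buried:
            raise ValueError(f"buried residues cannot be grafted: {buried}")

    return EpitopePatch(
        donor_id=donor.id,
        residues=tuple(residues),
        source_chain=chain,
    )


def superpose_epitope(
    patch: EpitopePatch,
    donor: Structure,
    scaffold: Structure,
    mapping: SiteMapping,
    scaffold_chain: Optional[str] = None,
    profile: Optional[ExposureProfile] = None,
    segments: Optional[Sequence[StrandSegment]] = None,
) -> GraftScore:
    """Score the structural match of a donor epitope to its scaffold sites.

    Donor Cα atoms of the patch are superposed (proper rotation only) onto
    the scaffold's rung-1 Cα atoms at the mapped positions.
    ``exposure_fraction`` is the fraction of target sites classified exposed
    when a classified profile is given (1.0 otherwise); the parity flag
    records whether mapped sites sharing a strand lie on one face.
    """
    donor_ca = donor.atom_coords(patch.source_chain, "CA")
    if scaffold_chain is None:
        chains = scaffold.chain_ids()
        if len(chains) != 1:
            raise ValueError("specify scaffold_chain for multi-chain scaffolds")
        scaffold_chain = chains[0]
    scaffold_ca = scaffold.atom_coords(scaffold_chain, "CA")

    mapped = [(d, p) for d, p in mapping.assignments if d in dict(patch.residues)]
    if len(mapped) < 3:
        raise ValueError(
            f"superposition underdetermined: only {len(mapped)} mapped positions"
        )
    missing_d = [d for d, _ in mapped if d not in donor_ca]
    missing_p = [p for _, p in mapped if p not in scaffold_ca]
    if missing_d or missing_p:
        raise ValueError(
            f"missing Cα atoms (donor {missing_d}, scaffold {missing_p})"
        )
    mobile = np.array([donor_ca[d] for d, _ in mapped])
    target = np.array([scaffold_ca[p] for _, p in mapped])
    _, _, rmsd = superpose(mobile, target)

    positions = [p for _, p in mapped]
    if profile is not None and profile.classes:
        exposed = sum(
            1
            for p in positions
            if profile.classes.get((scaffold_chain, p)) == "exposed"
        )
        exposure_fraction = exposed / len(positions)
    else:
        exposure_fraction = 1.0

    parity = True
    if segments:
        for seg in segments:
            inside = [p for p in positions if p in seg]
            if len(inside) >= 2:
                faces = strand_face_parity(scaffold, seg)
                labels = {faces[p] for p in inside}
                if len(labels) > 1:
                    parity = False
    else:
        # fall back to residue-number parity: same-face sites on one strand
        # are spaced by even author-number differences
        parity = len({p % 2 for p in positions}) == 1

    return GraftScore(
        ca_rmsd=rmsd,
        exposure_fraction=exposure_fraction,
        parity_consistent=parity,
    )


def design_stacked_graft(
    scaffold_seq: SequenceRecord,
    rung_map: RungMap,
    patch: EpitopePatch,
    mapping: SiteMapping,
    name: str,
    score: Optional[GraftScore] = None,
) -> ConstructDesign:
    """Emit the two-rung substitution set for one epitope graft.

    For each assignment ``donor residue x -> rung-1 position p`` the design
    places ``x`` at ``p`` (rung 1) and at ``p + Δ`` (rung 2).  Substitutions
    whose target letter equals the scaffold wild-type are identity-dropped
    and only counted, which is why rungs may print asymmetric lists.
    """
    donor_letters = dict(patch.residues)
    substitutions: list[Substitution] = []
    skipped = 0
    for donor_num, p1 in mapping.assignments:
        if donor_num not in donor_letters:
            raise ValueError(f"donor residue {donor_num} not in epitope patch")
        new = donor_letters[donor_num]
        if new == "X":
            raise ValueError(f"donor residue {donor_num} is non-standard")
        for rung, pos in ((1, p1), (2, rung_map.partner(p1))):
            if not (scaffold_seq.start_number <= pos <= scaffold_seq.end_number):
                raise ValueError(
                    f"rung-{rung} position {pos} outside scaffold sequence "
                    f"{scaffold_seq.start_number}-{scaffold_seq.end_number}"
                )
            wt = scaffold_seq.letter_at(pos)
            if wt == new:
                skipped += 1
                continue
            substitutions.append(Substitution(position=pos, wt=wt, new=new, rung=rung))
    substitutions.sort(key=lambda s: s.position)

    if score is not None:
        score = GraftScore(
            ca_rmsd=score.ca_rmsd,
            exposure_fraction=score.exposure_fraction,
            parity_consistent=score.parity_consistent,
            n_identity_skipped=skipped,
        )
    else:
        score = GraftScore(
            ca_rmsd=0.0,
            exposure_fraction=1.0,
            parity_consistent=True,
            n_identity_skipped=skipped,
        )

    return ConstructDesign(
        name=name,
        scaffold_id=scaffold_seq.id,
        substitutions=tuple(substitutions),
        provenance={
            "donor_id": patch.donor_id,
            "donor_chain": patch.source_chain,
            "epitope_residues": list(patch.numbers),
            "assignments": [list(a) for a in mapping.assignments],
            "rung_offset": rung_map.offset,
        },
        score=score,
    )


def validate_design(
    design: ConstructDesign,
    scaffold_seq: SequenceRecord,
    rung_map: RungMap,
) -> ValidationReport:
    """Check a design against the scaffold sequence and the stack-mimicry rule.

    Flags, without ever mutating the design:

    * wild-type letters that disagree with the scaffold sequence;
    * rung-pair asymmetries -- a substitution whose partner at ``±Δ`` is
      neither present with the same target letter nor explainable by
      identity-dropping;
    * positions outside the scaffold sequence or the rung ranges.
    """
    delta = rung_map.offset
    wt_mismatches: list[str] = []
    asymmetries: list[str] = []
    out_of_range: list[str] = []

    by_position = {s.position: s for s in design.substitutions}

    def seq_letter(pos: int) -> Optional[str]:
        if scaffold_seq.start_number <= pos <= scaffold_seq.end_number:
            return scaffold_seq.letter_at(pos)
        return None

    for s in design.substitutions:
        wt = seq_letter(s.position)
        if wt is None:
            out_of_range.append(
                f"{s.label}: position {s.position} outside scaffold "
                f"{scaffold_seq.start_number}-{scaffold_seq.end_number}"
            )
            continue
        if wt != s.wt:
            wt_mismatches.append(
                f"{s.label}: scaffold has {wt} at {s.position}, design says {s.wt}"
            )
        partner_pos = s.position + delta if s.rung == 1 else s.position - delta
        partner = by_position.get(partner_pos)
        if partner is not None and partner.rung != s.rung:
            if partner.new == s.new:
                continue  # symmetric pair
            asymmetries.append(
                f"{s.label}: partner {partner.label} at {partner_pos} grafts a "
                f"different letter ({partner.new} vs {s.new})"
            )
            continue
        partner_wt = seq_letter(partner_pos)
        if partner_wt is None:
            out_of_range.append(
                f"{s.label}: rung partner position {partner_pos} outside scaffold"
            )
        elif partner_wt != s.new:
            asymmetries.append(
                f"{s.label}: no partner substitution at {partner_pos} and "
                f"scaffold {partner_wt}{partner_pos} ≠ target {s.new} "
                "(not explainable by identity-dropping)"
            )
    return ValidationReport(
        wt_mismatches=tuple(wt_mismatches),
        asymmetries=tuple(asymmetries),
        out_of_range=tuple(out_of_range),
    )
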