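"""Deterministic synthetic coordinate generators with known ground truth.

Idealized beta-solenoids and parallel in-register fibrils are generated by
pure arithmetic (internal-coordinate chain building with fixed canonical
bond lengths and angles; no RNG anywhere), so rise, twist, rung offset and
register are known exactly and every geometry, SASA and grafting operation
can be exercised without external structure files.

Two convenience builders ship with the package:

* :func:`make_het_s_scaffold` -- a *synthetic* two-rung beta-solenoid model
  carrying the canonical HET-s(218-289) sequence (rise 4.8 Å/rung, four
  strands per rung, rung offset 36).  It is an idealized stand-in for the
  experimental scaffold structure, not a copy of any PDB entry.
* :func:`make_synuclein_like_fibril` -- a *synthetic* parallel in-register
  stack of extended chains carrying the human alpha-synuclein sequence,
  spaced at the canonical ~4.8 Å cross-beta rise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import AA1_TO_3, Atom, Structure

__all__ = [
    "SolenoidSpec",
    "FibrilSpec",
    "make_ideal_solenoid",
    "make_in_register_fibril",
    "make_ideal_strand",
    "make_ideal_helix",
    "make_het_s_scaffold",
    "make_synuclein_like_fibril",
    "HET_S_SEQUENCE",
    "HET_S_START",
    "ALPHA_SYNUCLEIN_SEQUENCE",
]

# canonical backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = 122.6  # L-chirality improper
OMEGA = 180.0

# dihedrals used for idealized conformations
PHI_BETA, PSI_BETA = -135.0, 135.0
PHI_TURN, PSI_TURN = -60.0, -30.0
PHI_HELIX, PSI_HELIX = -57.0, -47.0

#: canonical HET-s(218-289) prion-domain sequence, author numbering 218-289
HET_S_SEQUENCE = (
    "KIDAIVGRNSAKDIRTEERARVQLGNVVTAAALHGGIRISDQTTNSVETVVGKGESRVLIGNEYGGKGFWDN"
)
HET_S_START = 218

#: human alpha-synuclein, 140 residues; the fibril core / NAC region spans
#: residues 61-95
ALPHA_SYNUCLEIN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTKEQVTNVGGAVVT"
    "GVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDPDNEAYEMPSEEGYQDYEPEA"
)


# ---------------------------------------------------------------------------
# internal-coordinate chain building (NeRF)
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D with |C-D| = bond, angle(B,C,D) and torsion(A,B,C,D)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.column_stack([bc_hat, np.cross(n_hat, bc_hat), n_hat])
    return m @ d_local + c


def build_backbone(
    dihedrals: Sequence[tuple[float, float]],
) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O (+ideal CB) coordinates from per-residue (phi, psi)."""
    n_res = len(dihedrals)
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    for i, (phi, psi) in enumerate(dihedrals):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            ang = math.radians(ANGLE_N_CA_C)
            # place C in the xy-plane at the canonical N-CA-C angle
            c = ca + BOND_CA_C * np.array(
                [math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0]
            )
        else:
            prev = residues[-1]
            psi_prev = dihedrals[i - 1][1]
            n = _place(prev["N"], prev["CA"], prev["C"],
                       BOND_C_N, ANGLE_CA_C_N, psi_prev)
            ca = _place(prev["CA"], prev["C"], n,
                        BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c = _place(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    for i, (phi, psi) in enumerate(dihedrals):
        res = residues[i]
        res["O"] = _place(res["N"], res["CA"], res["C"],
                          BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        res["CB"] = _place(res["N"], res["C"], res["CA"],
                           BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
    return residues


def _rotation_about_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([
        [math.cos(t), -math.sin(t), 0.0],
        [math.sin(t), math.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])


def _orient_plane_to_z(coords: dict[int, dict[str, np.ndarray]]) -> np.ndarray:
    """Rotation putting the point cloud's thinnest direction along z."""
    ca = np.array([res["CA"] for res in coords.values()])
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    s = np.linalg.norm(v)
    c = float(normal @ z)
    if s < 1e-12:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _atoms_from_residues(
    residues: Sequence[dict[str, np.ndarray]],
    sequence: str,
    start_number: int,
    chain_id: str,
    serial_start: int = 1,
) -> list[Atom]:
    atoms: list[Atom] = []
    serial = serial_start
    for i, res in enumerate(residues):
        one = sequence[i]
        name3 = AA1_TO_3.get(one, "ALA")
        for atom_name in ("N", "CA", "C", "O", "CB"):
            if atom_name == "CB" and name3 == "GLY":
                continue
            xyz = res[atom_name]
            atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    element="N" if atom_name == "N" else
                            ("O" if atom_name == "O" else "C"),
                    coord=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    residue_name=name3,
                    residue_number=start_number + i,
                    chain_id=chain_id,
                )
            )
            serial += 1
    return atoms


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolenoidSpec:
    """Ground-truth parameters of an idealized beta-solenoid."""

    n_rungs: int = 2
    residues_per_rung: int = 36
    rise: float = 4.8  # Å per rung
    twist: float = -1.0  # degrees per rung (left-handed when negative)
    strand_layout: tuple[tuple[int, int], ...] = ((3, 3), (7, 1), (7, 2), (8, 5))
    sequence: Optional[str] = None
    start_number: int = 1

    def __post_init__(self) -> None:
        if self.n_rungs < 2:
            raise ValueError("a solenoid needs at least 2 rungs")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        total = sum(s + t for s, t in self.strand_layout)
        if total != self.residues_per_rung:
            raise ValueError(
                f"strand_layout sums to {total}, expected {self.residues_per_rung}"
            )
        if any(s < 1 or t < 0 for s, t in self.strand_layout):
            raise ValueError("strand lengths must be ≥1 and turns ≥0")
        if self.sequence is not None and (
            len(self.sequence) != self.n_rungs * self.residues_per_rung
        ):
            raise ValueError(
                f"sequence length {len(self.sequence)} ≠ "
                f"{self.n_rungs} × {self.residues_per_rung}"
            )


@dataclass(frozen=True)
class FibrilSpec:
    """Ground-truth parameters of an idealized cross-beta fibril stack."""

    n_chains: int = 2
    rise: float = 4.8  # Å per chain
    twist: float = 0.0  # degrees per chain
    sequence: str = "VVTGVTAVAQ"
    start_number: int = 1
    register_shift: int = 0  # 0 = in-register ground truth
    orientation: str = "parallel"  # {"parallel", "antiparallel"}

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("a fibril stack needs at least 2 chains")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError("orientation must be parallel or antiparallel")
        if len(self.sequence) < 3:
            raise ValueError("sequence too short")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rung_dihedrals(layout: Sequence[tuple[int, int]]) -> list[tuple[float, float]]:
    dihedrals: list[tuple[float, float]] = []
    for strand_len, turn_len in layout:
        dihedrals += [(PHI_BETA, PSI_BETA)] * strand_len
        dihedrals += [(PHI_TURN, PSI_TURN)] * turn_len
    return dihedrals


def make_ideal_solenoid(spec: SolenoidSpec, structure_id: str = "ideal_solenoid") -> Structure:
    """Generate an idealized beta-solenoid as a single chain.

    Rung 0 is built once from backbone dihedrals (beta strands separated by
    non-beta turns per ``strand_layout``), oriented with its mean plane
    normal along z; rung ``k`` is rung 0 rotated by ``k × twist`` about z
    and translated ``k × rise`` along z.  Fully deterministic.
    """
    per_rung = spec.residues_per_rung
    sequence = spec.sequence or "A" * (spec.n_rungs * per_rung)
    dihedrals = _rung_dihedrals(spec.strand_layout)
    rung0 = build_backbone(dihedrals)
    coords0 = {i: rung0[i] for i in range(per_rung)}
    rot_to_plane = _orient_plane_to_z(coords0)
    ca = np.array([res["CA"] for res in rung0])
    center = ca.mean(axis=0)
    base = [
        {k: rot_to_plane @ (v - center) for k, v in res.items()} for res in rung0
    ]

    atoms: list[Atom] = []
    serial = 1
    for k in range(spec.n_rungs):
        rot = _rotation_about_z(spec.twist * k)
        shift = np.array([0.0, 0.0, spec.rise * k])
        rung_res = [
            {name: rot @ xyz + shift for name, xyz in res.items()} for res in base
        ]
        seq_slice = sequence[k * per_rung : (k + 1) * per_rung]
        new_atoms = _atoms_from_residues(
            rung_res,
            seq_slice,
            spec.start_number + k * per_rung,
            chain_id="A",
            serial_start=serial,
        )
        serial += len(new_atoms)
        atoms += new_atoms
    return Structure(atoms=atoms, id=structure_id, source_format="synthetic")


def make_in_register_fibril(
    spec: FibrilSpec,
    chain_template: Optional[Sequence[tuple[float, float]]] = None,
    structure_id: str = "ideal_fibril",
) -> Structure:
    """Generate an idealized cross-beta stack of identical chains.

    The template chain (extended beta conformation unless per-residue
    dihedrals are supplied) is oriented with its long axis in the xy-plane;
    chain ``k`` is the template rotated by ``k × twist`` about z and
    translated ``k × rise`` along z.  ``orientation="antiparallel"`` flips
    alternate chains 180° about z (reversing their N→C direction);
    ``register_shift`` offsets the author numbering of alternate chains,
    modelling a sheet whose chains are sequence-shifted out of register.
    """
    n_res = len(spec.sequence)
    dihedrals = chain_template or [(PHI_BETA, PSI_BETA)] * n_res
    if len(dihedrals) != n_res:
        raise ValueError("chain_template length must match sequence length")
    template = build_backbone(dihedrals)
    ca = np.array([res["CA"] for res in template])
    center = ca.mean(axis=0)
    # long axis -> x, thinnest axis -> z
    centered = ca - center
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    frame = np.vstack([vt[0], np.cross(vt[2], vt[0]), vt[2]])
    base = [
        {k: frame @ (v - center) for k, v in res.items()} for res in template
    ]

    atoms: list[Atom] = []
    serial = 1
    for k in range(spec.n_chains):
        chain_id = chr(ord("A") + k)
        rot = _rotation_about_z(spec.twist * k)
        if spec.orientation == "antiparallel" and k % 2 == 1:
            rot = rot @ _rotation_about_z(180.0)
        shift = np.array([0.0, 0.0, spec.rise * k])
        chain_res = [
            {name: rot @ xyz + shift for name, xyz in res.items()} for res in base
        ]
        start = spec.start_number + (spec.register_shift if k % 2 == 1 else 0)
        new_atoms = _atoms_from_residues(
            chain_res, spec.sequence, start, chain_id=chain_id, serial_start=serial
        )
        serial += len(new_atoms)
        atoms += new_atoms
    return Structure(atoms=atoms, id=structure_id, source_format="synthetic")


def make_ideal_helix(n_res: int = 10, sequence: Optional[str] = None) -> Structure:
    """An ideal alpha-helix (negative control for strand segmentation)."""
    seq = sequence or "A" * n_res
    residues = build_backbone([(PHI_HELIX, PSI_HELIX)] * n_res)
    atoms = _atoms_from_residues(residues, seq, start_number=1, chain_id="A")
    return Structure(atoms=atoms, id="ideal_helix", source_format="synthetic")


def make_ideal_strand(n_res: int = 10, sequence: Optional[str] = None,
                      start_number: int = 1) -> Structure:
    """An ideal extended beta strand."""
    seq = sequence or "A" * n_res
    residues = build_backbone([(PHI_BETA, PSI_BETA)] * n_res)
    atoms = _atoms_from_residues(residues, seq, start_number=start_number,
                                 chain_id="A")
    return Structure(atoms=atoms, id="ideal_strand", source_format="synthetic")


# ---------------------------------------------------------------------------
# study-system stand-ins
# ---------------------------------------------------------------------------

def make_het_s_scaffold(rise: float = 4.8, twist: float = -1.0) -> Structure:
    """Synthetic idealized model of the HET-s(218-289) two-rung beta-solenoid.

    Carries the canonical 72-residue prion-domain sequence in author
    numbering 218-289, with 36 residues (four beta strands) per rung and the
    canonical ~4.8 Å inter-rung rise.  This is an idealized *synthetic*
    stand-in built from internal coordinates -- use a real structure file
    for experimental geometry.
    """
    spec = SolenoidSpec(
        n_rungs=2,
        residues_per_rung=36,
        rise=rise,
        twist=twist,
        strand_layout=((3, 3), (7, 1), (7, 2), (8, 5)),
        sequence=HET_S_SEQUENCE,
        start_number=HET_S_START,
    )
    return make_ideal_solenoid(spec, structure_id="HETs_218-289_synthetic")


def make_synuclein_like_fibril(
    n_chains: int = 3,
    rise: float = 4.8,
    twist: float = 0.0,
    residue_range: tuple[int, int] = (61, 95),
) -> Structure:
    """Synthetic parallel in-register fibril carrying the alpha-synuclein
    sequence (default: the NAC fibril-core region, residues 61-95).

    An idealized extended-chain stack at the canonical cross-beta spacing --
    a *synthetic* stand-in for experimental fibril structures.
    """
    lo, hi = residue_range
    if not (1 <= lo < hi <= len(ALPHA_SYNUCLEIN_SEQUENCE)):
        raise ValueError(f"residue_range {residue_range} outside 1-140")
    seq = ALPHA_SYNUCLEIN_SEQUENCE[lo - 1 : hi]
    spec = FibrilSpec(
        n_chains=n_chains,
        rise=rise,
        twist=twist,
        sequence=seq,
        start_number=lo,
    )
    return make_in_register_fibril(spec, structure_id="asyn_fibril_synthetic")
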