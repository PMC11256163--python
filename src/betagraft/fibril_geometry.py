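"""Cross-beta fibril and beta-solenoid geometry.

A cross-beta amyloid stacks identical repeats (whole chains, or rungs of a
solenoid) along a common axis with an axial rise of ~4.8 Å per repeat and a
small twist.  This module measures that architecture:

* :func:`estimate_fibril_frame` -- least-squares screw fit over corresponding
  Cα pairs, giving axis, rise (Å/repeat) and twist (deg/repeat);
* :func:`segment_strands` -- backbone-dihedral beta-strand segmentation;
* :func:`detect_rung_offset` -- the solenoid's internal pseudo-repeat Δ, i.e.
  the author-number shift mapping rung-1 positions onto rung-2 positions;
* :func:`check_in_register` -- verification that stacked chains form a
  parallel in-register beta-sheet.

All residue intervals are inclusive and use author numbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Structure

__all__ = [
    "HelicalParameters",
    "StrandSegment",
    "RungMap",
    "RegisterReport",
    "superpose",
    "estimate_fibril_frame",
    "segment_strands",
    "detect_rung_offset",
    "check_in_register",
    "NoSolenoidRepeatError",
]

# strand acceptance window for backbone dihedrals, degrees
PHI_STRAND = (-180.0, -45.0)
PSI_STRAND = (45.0, 225.0)  # interpreted mod 360
DEFAULT_MIN_STRAND_LEN = 3
DEFAULT_RUNG_RMSD_THRESHOLD = 3.0  # Å; the solenoid pseudo-repeat is approximate
DEFAULT_MIN_ALIGNED = 15
DEFAULT_REGISTER_TOLERANCE = 2.4  # Å; half the canonical 4.8 Å rise


class NoSolenoidRepeatError(ValueError):
    """No candidate rung offset gave an acceptable superposition RMSD."""


@dataclass(frozen=True)
class HelicalParameters:
    """Screw parameters relating successive repeats of a fibril or solenoid."""

    axis_direction: tuple[float, float, float]
    axis_point: tuple[float, float, float]
    rise: float  # Å per repeat
    twist: float  # degrees per repeat, in (-180, 180]
    repeat_kind: str  # {"inter_chain", "intra_chain_rung"}
    rmsd: float  # Å, repeat superposition

    def __post_init__(self) -> None:
        n = float(np.linalg.norm(self.axis_direction))
        if abs(n - 1.0) > 1e-6:
            raise ValueError("axis_direction must be a unit vector")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180]")


@dataclass(frozen=True)
class StrandSegment:
    chain_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.end_residue < self.start_residue:
            raise ValueError("segment end before start")

    def __len__(self) -> int:
        return self.end_residue - self.start_residue + 1

    def __contains__(self, residue_number: int) -> bool:
        return self.start_residue <= residue_number <= self.end_residue


@dataclass(frozen=True)
class RungMap:
    """Correspondence between rung-1 and rung-2 positions of a solenoid.

    ``offset`` is the author-number difference Δ = rung2 − rung1; every pair
    satisfies ``rung2 == rung1 + offset``.
    """

    offset: int
    pairs: tuple[tuple[int, int], ...]
    rung1_range: tuple[int, int]
    rung2_range: tuple[int, int]
    alignment_rmsd: float

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("rung offset must be positive")
        for r1, r2 in self.pairs:
            if r2 != r1 + self.offset:
                raise ValueError(f"pair ({r1}, {r2}) violates offset {self.offset}")

    def partner(self, rung1_position: int) -> int:
        return rung1_position + self.offset


@dataclass(frozen=True)
class RegisterReport:
    per_residue_axial_offset: dict[int, float]
    max_offset: float
    orientation: str  # {"parallel", "antiparallel", "mixed"}
    in_register: bool


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation least-squares superposition (Kabsch).

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile onto target;
    ``det(R) = +1`` always (no reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    rmsd = float(rssd) / math.sqrt(n)
    return R, t, rmsd


def _screw_parameters(
    R: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Decompose a rigid motion into screw axis, twist (deg), rise and a point.

    The axis is oriented so the rise is positive; for a (near-)pure
    translation the axis is the translation direction and the twist is 0.
    """
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-8:
        norm_t = float(np.linalg.norm(t))
        if norm_t < 1e-9:
            raise ValueError("degenerate repeat transform (identity)")
        axis = t / norm_t
        return axis, 0.0, norm_t, np.zeros(3)
    axis = rotvec / angle
    rise = float(t @ axis)
    if rise < 0:
        axis = -axis
        angle = -angle
        rise = -rise
    # point on axis: (I - R) p = t_perp, constrained to the plane p.axis = 0
    t_perp = t - (t @ axis) * axis
    A = np.vstack([np.eye(3) - R, axis[None, :]])
    b = np.concatenate([t_perp, [0.0]])
    point, *_ = np.linalg.lstsq(A, b, rcond=None)
    twist = math.degrees(angle)
    if twist <= -180.0:
        twist += 360.0
    return axis, twist, rise, point


def _collect_repeat_coords(
    structure: Structure,
    chains: Optional[Sequence[str]],
    rung_intervals: Optional[Sequence[tuple[int, int]]],
    chain: Optional[str],
) -> tuple[list[np.ndarray], str]:
    """Build equal-length Cα coordinate arrays, one per repeat, in stack order."""
    if (chains is None) == (rung_intervals is None):
        raise ValueError("give exactly one of chains= or rung_intervals=")
    if chains is not None:
        if len(chains) < 2:
            raise ValueError("need at least 2 chains to define a repeat")
        maps = [structure.atom_coords(c, "CA") for c in chains]
        common = sorted(set.intersection(*[set(m) for m in maps]))
        if len(common) < 3:
            raise ValueError(
                f"chains {list(chains)} share only {len(common)} Cα-bearing "
                "residues with common author numbers"
            )
        coords = [np.array([m[r] for r in common]) for m in maps]
        return coords, "inter_chain"

    if len(rung_intervals) < 2:
        raise ValueError("need at least 2 rung intervals")
    if chain is None:
        chain_ids = None
        for m in structure.model_ids():
            chain_ids = structure.chain_ids(m)
            break
        if not chain_ids or len(chain_ids) != 1:
            raise ValueError("specify chain= for intra-chain rung repeats")
        chain = chain_ids[0]
    lengths = {hi - lo + 1 for lo, hi in rung_intervals}
    if len(lengths) != 1:
        raise ValueError(f"rung intervals of unequal length: {rung_intervals}")
    camap = structure.atom_coords(chain, "CA")
    coords = []
    for lo, hi in rung_intervals:
        missing = [r for r in range(lo, hi + 1) if r not in camap]
        if missing:
            raise ValueError(
                f"rung interval ({lo}, {hi}) lacks Cα for residues {missing}"
            )
        coords.append(np.array([camap[r] for r in range(lo, hi + 1)]))
    return coords, "intra_chain_rung"


def estimate_fibril_frame(
    structure: Structure,
    chains: Optional[Sequence[str]] = None,
    rung_intervals: Optional[Sequence[tuple[int, int]]] = None,
    chain: Optional[str] = None,
) -> HelicalParameters:
    """Fit the helical (screw) frame relating successive repeats.

    The repeat is either ``chains`` -- an ordered list of chain ids stacked
    along the fibril (corresponding residues share author numbers) -- or
    ``rung_intervals`` -- two or more equal-length author-number intervals of
    one chain (the rungs of a solenoid; pass ``chain=`` when the structure
    has several chains).

    Rise is the mean axial translation per repeat, twist the mean rotation
    about the fitted axis, and ``rmsd`` the mean Cα superposition RMSD of
    successive repeat pairs.
    """
    coords, kind = _collect_repeat_coords(structure, chains, rung_intervals, chain)
    axes, twists, rises, rmsds = [], [], [], []
    axis_point = np.zeros(3)
    for k in range(len(coords) - 1):
        R, t, rmsd = superpose(coords[k], coords[k + 1])
        axis, twist, rise, point = _screw_parameters(R, t)
        if axes and axis @ axes[0] < 0:
            axis, twist = -axis, -twist
        axes.append(axis)
        twists.append(twist)
        rises.append(rise)
        rmsds.append(rmsd)
        if k == 0:
            axis_point = point
    mean_axis = np.mean(axes, axis=0)
    mean_axis /= np.linalg.norm(mean_axis)
    return HelicalParameters(
        axis_direction=tuple(mean_axis),
        axis_point=tuple(axis_point),
        rise=float(np.mean(rises)),
        twist=float(np.mean(twists)),
        repeat_kind=kind,
        rmsd=float(np.mean(rmsds)),
    )


# ---------------------------------------------------------------------------
# beta-strand segmentation
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention: cis = 0)."""
    b0 = np.subtract(p0, p1)
    b1 = np.subtract(p2, p1)
    b2 = np.subtract(p3, p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(
    structure: Structure, chain: str, residue_range: Optional[tuple[int, int]] = None
) -> dict[int, tuple[Optional[float], Optional[float]]]:
    """Per-residue (phi, psi) in degrees; None where a neighbor is missing."""
    n_map = structure.atom_coords(chain, "N")
    ca_map = structure.atom_coords(chain, "CA")
    c_map = structure.atom_coords(chain, "C")
    complete = set(n_map) & set(ca_map) & set(c_map)
    partial = (set(n_map) | set(ca_map) | set(c_map)) - complete
    if residue_range is not None:
        lo, hi = residue_range
        complete = {r for r in complete if lo <= r <= hi}
        partial = {r for r in partial if lo <= r <= hi}
    if partial:
        raise ValueError(f"missing backbone atoms for residues {sorted(partial)}")
    residues = sorted(complete)
    out: dict[int, tuple[Optional[float], Optional[float]]] = {}
    res_set = set(residues)
    for r in residues:
        phi = psi = None
        if r - 1 in res_set:
            phi = _dihedral(c_map[r - 1], n_map[r], ca_map[r], c_map[r])
        if r + 1 in res_set:
            psi = _dihedral(n_map[r], ca_map[r], c_map[r], n_map[r + 1])
        out[r] = (phi, psi)
    return out


def _is_strand_like(phi: Optional[float], psi: Optional[float]) -> bool:
    # chain termini have only one defined dihedral; judge by what exists
    if phi is None and psi is None:
        return False
    if phi is not None and not (PHI_STRAND[0] <= phi <= PHI_STRAND[1]):
        return False
    if psi is not None:
        psi_mod = psi % 360.0
        if not (PSI_STRAND[0] <= psi_mod <= PSI_STRAND[1]):
            return False
    return True


def segment_strands(
    structure: Structure,
    chain: str,
    residue_range: Optional[tuple[int, int]] = None,
    min_strand_len: int = DEFAULT_MIN_STRAND_LEN,
) -> list[StrandSegment]:
    """Segment a chain into beta strands by backbone dihedrals.

    A residue is strand-like when φ ∈ [−180°, −45°] and ψ (mod 360°) ∈
    [45°, 225°]; contiguous strand-like runs of at least ``min_strand_len``
    residues become segments.  Deterministic for fixed input.
    """
    dihedrals = backbone_dihedrals(structure, chain, residue_range)
    residues = sorted(dihedrals)
    segments: list[StrandSegment] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_strand_len:
            segments.append(StrandSegment(chain, run[0], run[-1]))
        run.clear()

    for r in residues:
        if run and r != run[-1] + 1:
            flush()
        if _is_strand_like(*dihedrals[r]):
            run.append(r)
        else:
            flush()
    flush()
    return segments


# ---------------------------------------------------------------------------
# solenoid rung offset
# ---------------------------------------------------------------------------

def detect_rung_offset(
    structure: Structure,
    chain: str,
    search_range: tuple[int, int] = (4, 60),
    rmsd_threshold: float = DEFAULT_RUNG_RMSD_THRESHOLD,
    min_aligned: int = DEFAULT_MIN_ALIGNED,
) -> RungMap:
    """Find the solenoid's internal pseudo-repeat offset Δ.

    For each candidate Δ in ``search_range`` (inclusive), the Cα set at
    author positions {i} is superposed onto the set at {i+Δ} over the maximal
    overlapping window; the Δ with the lowest RMSD wins, ties going to the
    smaller Δ.  A :class:`NoSolenoidRepeatError` is raised when no candidate
    achieves ``rmsd_threshold`` over at least ``min_aligned`` pairs.
    """
    camap = structure.atom_coords(chain, "CA")
    residues = sorted(camap)
    if len(residues) < 2 * min_aligned:
        raise ValueError(
            f"chain {chain!r} has {len(residues)} Cα; too short for two rungs "
            f"of ≥{min_aligned} residues"
        )
    lo, hi = search_range
    if lo < 1:
        raise ValueError("search_range must start at ≥1")
    best: Optional[tuple[float, int, list[int]]] = None
    for delta in range(lo, hi + 1):
        window = [r for r in residues if r + delta in camap]
        if len(window) < min_aligned:
            continue
        a = np.array([camap[r] for r in window])
        b = np.array([camap[r + delta] for r in window])
        _, _, rmsd = superpose(a, b)
        if rmsd <= rmsd_threshold and (best is None or rmsd < best[0] - 1e-12):
            best = (rmsd, delta, window)
    if best is None:
        raise NoSolenoidRepeatError(
            f"no solenoid repeat detected in Δ ∈ [{lo}, {hi}] "
            f"(RMSD threshold {rmsd_threshold} Å over ≥{min_aligned} Cα)"
        )
    rmsd, delta, window = best
    pairs = tuple((r, r + delta) for r in window)
    return RungMap(
        offset=delta,
        pairs=pairs,
        rung1_range=(window[0], window[-1]),
        rung2_range=(window[0] + delta, window[-1] + delta),
        alignment_rmsd=rmsd,
    )


# ---------------------------------------------------------------------------
# parallel in-register check
# ---------------------------------------------------------------------------

def check_in_register(
    structure: Structure,
    chains: Sequence[str],
    tolerance: float = DEFAULT_REGISTER_TOLERANCE,
) -> RegisterReport:
    """Verify that stacked chains form a parallel in-register sheet.

    For every residue shared by successive chains, the Cα displacement is
    compared with the ideal rise translation along the fitted fibril axis;
    the reported per-residue offset is the magnitude of the deviation (axial
    plus lateral, so a register shift perpendicular to the axis is caught).
    ``in_register`` requires a parallel orientation and max offset within
    ``tolerance``.
    """
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    maps = [structure.atom_coords(c, "CA") for c in chains]
    common = sorted(set.intersection(*[set(m) for m in maps]))
    if len(common) < 3:
        raise ValueError(f"chains {list(chains)} share too few residues")

    # chain N->C direction agreement
    dirs = []
    for m in maps:
        res = sorted(m)
        v = np.subtract(m[res[-1]], m[res[0]])
        dirs.append(v / np.linalg.norm(v))
    signs = [float(np.dot(dirs[k], dirs[k + 1])) for k in range(len(dirs) - 1)]
    if all(s > 0 for s in signs):
        orientation = "parallel"
    elif all(s < 0 for s in signs):
        orientation = "antiparallel"
    else:
        orientation = "mixed"

    frame = estimate_fibril_frame(structure, chains=list(chains))
    axis = np.array(frame.axis_direction)
    rise = frame.rise
    if abs(frame.twist) < 0.5:
        # Pure-translation degenerate case: a correspondence slipped along the
        # chain would be absorbed into the fitted axis.  Re-anchor the axis as
        # the component of the mean displacement orthogonal to the chain
        # tangent, so in-chain slip shows up as deviation, not as axis tilt.
        t_mean = np.mean(
            [np.subtract(maps[1][r], maps[0][r]) for r in common], axis=0
        )
        tangent = dirs[0]
        axial = t_mean - (t_mean @ tangent) * tangent
        if np.linalg.norm(axial) > 1e-6:
            axis = axial / np.linalg.norm(axial)
            rise = float(np.linalg.norm(axial))
    ideal = rise * axis

    per_residue: dict[int, float] = {}
    for r in common:
        worst = 0.0
        for k in range(len(chains) - 1):
            d = np.subtract(maps[k + 1][r], maps[k][r])
            worst = max(worst, float(np.linalg.norm(d - ideal)))
        per_residue[r] = worst
    max_offset = max(per_residue.values())
    return RegisterReport(
        per_residue_axial_offset=per_residue,
        max_offset=max_offset,
        orientation=orientation,
        in_register=(orientation == "parallel" and max_offset <= tolerance),
    )
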