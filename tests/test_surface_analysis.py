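"""Solvent accessibility, exposure classes and strand faces."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from betagraft.fibril_geometry import segment_strands
from betagraft.structure_io import Atom, Structure
from betagraft.surface_analysis import (
    classify_exposure,
    compute_sasa,
    golden_spiral_points,
    stack_repeats,
    strand_face_parity,
)
from betagraft.synthetic_fixtures import (
    ALPHA_SYNUCLEIN_SEQUENCE,
    FibrilSpec,
    make_ideal_strand,
    make_in_register_fibril,
)


def _carbon(serial, xyz, residue=1, chain="A"):
    return Atom(
        serial=serial,
        name="C",
        element="C",
        coord=xyz,
        residue_name="ALA",
        residue_number=residue,
        chain_id=chain,
    )


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        """Carbon (vdW 1.70 Å) + 1.4 Å probe: SASA = 4π(3.10)² ≈ 120.8 Å²."""
        st = Structure(atoms=[_carbon(1, (0.0, 0.0, 0.0))], id="c")
        profile = compute_sasa(st, n_sphere_points=960)
        analytic = 4.0 * math.pi * (1.70 + 1.4) ** 2
        assert profile.per_residue_sasa[("A", 1)] == pytest.approx(
            analytic, rel=0.02
        )

    def test_distant_atoms_are_additive(self):
        st = Structure(
            atoms=[_carbon(1, (0.0, 0.0, 0.0), 1), _carbon(2, (100.0, 0.0, 0.0), 2)],
            id="pair",
        )
        profile = compute_sasa(st)
        single = 4.0 * math.pi * (1.70 + 1.4) ** 2
        assert sum(profile.per_residue_sasa.values()) == pytest.approx(
            2 * single, rel=0.02
        )

    def test_fully_caged_atom_has_zero_sasa(self):
        atoms = [_carbon(1, (0.0, 0.0, 0.0), 1)]
        for i, p in enumerate(golden_spiral_points(60) * 3.4):
            atoms.append(_carbon(i + 2, tuple(p), residue=2))
        profile = compute_sasa(Structure(atoms=atoms, id="cage"))
        assert profile.per_residue_sasa[("A", 1)] == 0.0

    def test_point_count_convergence(self, scaffold):
        low = sum(compute_sasa(scaffold, n_sphere_points=960).per_residue_sasa.values())
        high = sum(
            compute_sasa(scaffold, n_sphere_points=1920).per_residue_sasa.values()
        )
        assert abs(high - low) / high < 0.01

    def test_rigid_motion_invariance(self, scaffold):
        base = sum(compute_sasa(scaffold).per_residue_sasa.values())
        R = Rotation.random(random_state=5).as_matrix()
        t = np.array([13.0, -40.0, 8.5])
        atoms = [
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                coord=tuple(R @ np.array(a.coord) + t),
                residue_name=a.residue_name,
                residue_number=a.residue_number,
                chain_id=a.chain_id,
            )
            for a in scaffold.atoms
        ]
        moved = Structure(atoms=atoms, id="moved")
        got = sum(compute_sasa(moved).per_residue_sasa.values())
        assert abs(got - base) / base < 1e-6

    def test_matches_independent_shrake_rupley(self):
        """Cross-check against biotite's Shrake-Rupley with identical radii."""
        import biotite.structure as bst

        st = make_ideal_strand(8, sequence="ARNDQEGH")
        mine = compute_sasa(st, n_sphere_points=1920)
        arr = bst.AtomArray(len(st.atoms))
        arr.coord = np.array([a.coord for a in st.atoms], dtype=np.float32)
        arr.chain_id = np.array([a.chain_id for a in st.atoms])
        arr.res_id = np.array([a.residue_number for a in st.atoms])
        arr.res_name = np.array([a.residue_name for a in st.atoms])
        arr.atom_name = np.array([a.name for a in st.atoms])
        arr.element = np.array([a.element for a in st.atoms])
        radii = np.array(
            [{"C": 1.70, "N": 1.55, "O": 1.52}[a.element] for a in st.atoms]
        )
        per_atom = bst.sasa(arr, point_number=1920, vdw_radii=radii)
        for r in range(1, 9):
            theirs = per_atom[arr.res_id == r].sum()
            assert mine.per_residue_sasa[("A", r)] == pytest.approx(
                theirs, rel=0.03
            )

    def test_zero_atoms_errors(self):
        with pytest.raises(ValueError):
            compute_sasa(Structure(atoms=[], id="empty"))

    def test_bad_parameters_error(self, scaffold):
        with pytest.raises(ValueError):
            compute_sasa(scaffold, probe_radius=-1.0)
        with pytest.raises(ValueError):
            compute_sasa(scaffold, n_sphere_points=50)


class TestClassification:
    def test_extremes(self):
        st = Structure(atoms=[_carbon(1, (0.0, 0.0, 0.0), 1)], id="c")
        profile = compute_sasa(st, reference_max={"ALA": 1.0})
        classified = classify_exposure(profile)
        assert classified.classes[("A", 1)] == "exposed"  # relative >> 1
        atoms = [_carbon(1, (0.0, 0.0, 0.0), 1)]
        for i, p in enumerate(golden_spiral_points(60) * 3.4):
            atoms.append(_carbon(i + 2, tuple(p), residue=2))
        caged = classify_exposure(
            compute_sasa(Structure(atoms=atoms, id="cage"))
        )
        assert caged.classes[("A", 1)] == "buried"

    def test_threshold_ordering_enforced(self, scaffold_exposure):
        with pytest.raises(ValueError):
            classify_exposure(scaffold_exposure, 0.05, 0.25)

    def test_graft_sites_not_buried_on_scaffold(self, scaffold_exposure):
        """Every published substitution position must be a surface position."""
        rung1 = [225, 227, 229, 230, 232, 234, 235, 236]
        for site in rung1 + [p + 36 for p in rung1]:
            assert scaffold_exposure.classes[("A", site)] in {
                "exposed",
                "intermediate",
            }

    def test_gxg_reference_is_self_consistent(self, cbeta_reference):
        st = make_ideal_strand(3, sequence="GVG")
        profile = compute_sasa(st, reference_max=cbeta_reference)
        assert profile.per_residue_relative[("A", 2)] == pytest.approx(1.0, abs=1e-9)


class TestFibrilContext:
    def test_middle_repeat_less_exposed_than_end(self):
        fib = make_in_register_fibril(
            FibrilSpec(
                n_chains=5,
                sequence=ALPHA_SYNUCLEIN_SEQUENCE[60:95],
                start_number=61,
            )
        )
        profile = compute_sasa(fib)
        for r in range(61, 96):
            assert (
                profile.per_residue_sasa[("C", r)]
                <= profile.per_residue_sasa[("A", r)] + 1e-6
            )
        total_mid = sum(profile.per_residue_sasa[("C", r)] for r in range(61, 96))
        total_end = sum(profile.per_residue_sasa[("A", r)] for r in range(61, 96))
        assert total_mid < total_end

    def test_stack_repeats_builds_n_copies(self, scaffold):
        from betagraft.fibril_geometry import estimate_fibril_frame

        frame = estimate_fibril_frame(
            scaffold, rung_intervals=[(218, 253), (254, 289)], chain="A"
        )
        stack = stack_repeats(scaffold, frame, n_copies=3)
        assert len(stack.atoms) == 3 * len(scaffold.atoms)
        assert len(stack.chain_ids()) == 3


class TestStrandFaces:
    def test_ideal_strand_alternates_strictly(self):
        st = make_ideal_strand(10)
        seg = segment_strands(st, "A")[0]
        faces = strand_face_parity(st, seg)
        labels = [faces[r] for r in range(1, 11)]
        assert labels == ["face_A", "face_B"] * 5

    def test_glycine_gets_pseudo_cbeta(self):
        st = make_ideal_strand(8, sequence="AAAGAAAA")
        seg = segment_strands(st, "A")[0]
        faces = strand_face_parity(st, seg)
        assert [faces[r] for r in range(1, 9)] == ["face_A", "face_B"] * 4

    def test_even_spaced_scaffold_sites_share_a_face(self, scaffold):
        """Positions 225/227/229 are spaced by 2 on one strand: same face."""
        segs = segment_strands(scaffold, "A", residue_range=(218, 253))
        seg = next(s for s in segs if 225 in s)
        faces = strand_face_parity(scaffold, seg)
        assert faces[225] == faces[227] == faces[229]
        # parity oracle: equal residue-number parity within one strand
        assert len({faces[r] for r in (224, 226, 228, 230)}) == 1
        assert faces[224] != faces[225]

    def test_missing_calpha_errors(self):
        from betagraft.fibril_geometry import StrandSegment

        st = make_ideal_strand(5)
        with pytest.raises(ValueError, match="Cα"):
            strand_face_parity(st, StrandSegment("A", 1, 9))
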