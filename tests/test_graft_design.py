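"""The stacked-graft design procedure and its validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betagraft.graft_design import (
    EpitopePatch,
    SiteMapping,
    design_stacked_graft,
    extract_epitope,
    superpose_epitope,
    validate_design,
)
from betagraft.construct_builder import apply_design, load_preset
from betagraft.structure_io import Atom, Structure
from betagraft.surface_analysis import classify_exposure, compute_sasa
from betagraft.synthetic_fixtures import (
    ALPHA_SYNUCLEIN_SEQUENCE,
    make_synuclein_like_fibril,
)


def _patch(positions, letters, donor_id="donor"):
    return EpitopePatch(
        donor_id=donor_id,
        residues=tuple(zip(positions, letters)),
        source_chain="A",
    )


def _identity_mapping(positions, rung_map):
    return SiteMapping(
        assignments=tuple((p, p) for p in positions), rung_map=rung_map
    )


class TestExtractEpitope:
    def test_nac_core_patch(self):
        donor = make_synuclein_like_fibril(residue_range=(61, 95))
        patch = extract_epitope(donor, "A", list(range(61, 96)))
        assert len(patch.residues) == 35
        for num, letter in patch.residues:
            assert letter == ALPHA_SYNUCLEIN_SEQUENCE[num - 1]

    def test_absent_residue_errors(self):
        donor = make_synuclein_like_fibril(residue_range=(61, 95))
        with pytest.raises(ValueError, match="99"):
            extract_epitope(donor, "A", [61, 99])

    def test_buried_residue_rejected_in_strict_mode(self):
        donor = make_synuclein_like_fibril(n_chains=5, residue_range=(61, 95))
        # an extreme threshold classifies every residue buried
        profile = classify_exposure(
            compute_sasa(donor), exposed_threshold=10.0, buried_threshold=9.0
        )
        with pytest.raises(ValueError, match="buried"):
            extract_epitope(
                donor, "C", [70, 72], require_exposed=True, profile=profile
            )


class TestSuperposeEpitope:
    def _structures(self, rung_map):
        donor = make_synuclein_like_fibril(residue_range=(61, 95))
        return donor

    def test_translated_copy_rmsd_zero(self, scaffold, rung_map):
        # donor = the scaffold itself renumbered: exact geometric match
        shifted = Structure(
            atoms=[
                Atom(
                    serial=a.serial, name=a.name, element=a.element,
                    coord=(a.coord[0] + 11.0, a.coord[1] - 4.0, a.coord[2] + 2.0),
                    residue_name=a.residue_name, residue_number=a.residue_number,
                    chain_id=a.chain_id,
                )
                for a in scaffold.atoms
            ],
            id="shifted",
        )
        positions = (225, 227, 229, 232)
        patch = extract_epitope(shifted, "A", list(positions))
        mapping = _identity_mapping(positions, rung_map)
        score = superpose_epitope(patch, shifted, scaffold, mapping)
        assert score.ca_rmsd < 1e-6

    def test_mirror_image_scores_worse_than_proper_fit(self, scaffold, rung_map):
        """The no-reflection constraint must not reach the improper optimum."""
        # span strands and turns of both directions: a genuinely chiral set
        positions = (220, 223, 225, 228, 232, 237, 241, 245, 250)
        mirrored = Structure(
            atoms=[
                Atom(
                    serial=a.serial, name=a.name, element=a.element,
                    coord=(-a.coord[0], a.coord[1], a.coord[2]),
                    residue_name=a.residue_name, residue_number=a.residue_number,
                    chain_id=a.chain_id,
                )
                for a in scaffold.atoms
            ],
            id="mirror",
        )
        patch = extract_epitope(mirrored, "A", list(positions))
        mapping = _identity_mapping(positions, rung_map)
        score = superpose_epitope(patch, mirrored, scaffold, mapping)
        # brute-force improper optimum via plain SVD without determinant fix
        ca_m = mirrored.atom_coords("A", "CA")
        ca_s = scaffold.atom_coords("A", "CA")
        A = np.array([ca_m[p] for p in positions])
        B = np.array([ca_s[p] for p in positions])
        A0, B0 = A - A.mean(0), B - B.mean(0)
        U, S, Vt = np.linalg.svd(B0.T @ A0)
        improper = np.sqrt(
            max(((A0 @ (U @ Vt).T - B0) ** 2).sum() / len(A), 0.0)
        )
        assert score.ca_rmsd > 1e-3
        assert score.ca_rmsd > improper - 1e-9

    def test_rigid_motion_invariance(self, scaffold, rung_map):
        from scipy.spatial.transform import Rotation

        positions = (225, 227, 229, 232)
        donor = make_synuclein_like_fibril(residue_range=(61, 95))
        patch = extract_epitope(donor, "A", [70, 72, 74, 76])
        mapping = SiteMapping(
            assignments=tuple(zip((70, 72, 74, 76), positions)),
            rung_map=rung_map,
        )
        ref = superpose_epitope(patch, donor, scaffold, mapping)
        R = Rotation.random(random_state=9).as_matrix()
        moved = Structure(
            atoms=[
                Atom(
                    serial=a.serial, name=a.name, element=a.element,
                    coord=tuple(R @ np.array(a.coord) + np.array([5.0, 6.0, 7.0])),
                    residue_name=a.residue_name, residue_number=a.residue_number,
                    chain_id=a.chain_id,
                )
                for a in donor.atoms
            ],
            id="moved",
        )
        got = superpose_epitope(patch, moved, scaffold, mapping)
        assert got.ca_rmsd == pytest.approx(ref.ca_rmsd, abs=1e-6)

    def test_too_few_positions_errors(self, scaffold, rung_map):
        donor = make_synuclein_like_fibril(residue_range=(61, 95))
        patch = extract_epitope(donor, "A", [70, 72])
        mapping = SiteMapping(
            assignments=((70, 225), (72, 227)), rung_map=rung_map
        )
        with pytest.raises(ValueError, match="underdetermined"):
            superpose_epitope(patch, donor, scaffold, mapping)


class TestStackedGraft:
    """Regeneration of the published two-rung substitution sets."""

    @pytest.mark.parametrize(
        "name, letters, positions, expected_r1, expected_r2",
        [
            (
                "alpha-SC6",
                "KVEG",
                (232, 234, 235, 236),
                ("R232K", "E234V", "R236G"),
                ("V268K", "K270V", "G271E", "E272G"),
            ),
            (
                "alpha-SC8",
                "KQT",
                (225, 227, 229),
                ("R225K", "S227Q", "K229T"),
                ("T261K", "S263Q", "E265T"),
            ),
            (
                "alpha-SC9",
                "KVEA",
                (227, 229, 230, 232),
                ("S227K", "K229V", "D230E", "R232A"),
                ("S263K", "E265V", "T266E", "V268A"),
            ),
        ],
    )
    def test_regenerates_published_designs(
        self, scaffold_seq, rung_map, name, letters, positions, expected_r1,
        expected_r2,
    ):
        patch = _patch(positions, letters)
        design = design_stacked_graft(
            scaffold_seq, rung_map, patch,
            _identity_mapping(positions, rung_map), name=name,
        )
        assert design.rung_labels(1) == expected_r1
        assert design.rung_labels(2) == expected_r2

    def test_sc6_identity_drops_rung1_site_235(self, scaffold_seq, rung_map):
        """Scaffold already carries E at 235, so only rung-2 G271E appears."""
        patch = _patch((232, 234, 235, 236), "KVEG")
        design = design_stacked_graft(
            scaffold_seq, rung_map, patch,
            _identity_mapping((232, 234, 235, 236), rung_map), name="sc6",
        )
        assert design.score.n_identity_skipped == 1
        assert "G271E" in design.labels
        assert all(s.position != 235 for s in design.substitutions)

    def test_all_identity_donor_yields_empty_design(self, scaffold_seq, rung_map):
        # pick rung-1 positions whose rung-2 partner carries the same letter,
        # so the donor letter equals the wild type on both rungs
        positions = tuple(
            p
            for p in range(rung_map.rung1_range[0], rung_map.rung1_range[1] + 1)
            if scaffold_seq.letter_at(p)
            == scaffold_seq.letter_at(p + rung_map.offset)
        )[:3]
        assert len(positions) == 3
        letters = tuple(scaffold_seq.letter_at(p) for p in positions)
        design = design_stacked_graft(
            scaffold_seq, rung_map, _patch(positions, letters),
            _identity_mapping(positions, rung_map), name="identity",
        )
        assert design.substitutions == ()
        assert design.score.n_identity_skipped == 2 * len(positions)

    def test_idempotence_on_grafted_scaffold(self, scaffold_seq, rung_map):
        patch = _patch((225, 227, 229), "KQT")
        mapping = _identity_mapping((225, 227, 229), rung_map)
        first = design_stacked_graft(
            scaffold_seq, rung_map, patch, mapping, name="first"
        )
        mutant = apply_design(scaffold_seq, first)
        second = design_stacked_graft(
            mutant, rung_map, patch, mapping, name="second"
        )
        assert second.substitutions == ()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(min_value=224, max_value=248),
            min_size=3, max_size=6, unique=True,
        ),
        letters=st.lists(
            st.sampled_from("ARNDCQEGHILKMFPSTWYV"), min_size=6, max_size=6
        ),
    )
    def test_stack_mimicry_closure(self, scaffold_seq, rung_map, positions, letters):
        """After applying any design, position p and p+Δ carry equal letters."""
        positions = sorted(positions)
        patch = _patch(positions, letters[: len(positions)])
        design = design_stacked_graft(
            scaffold_seq, rung_map, patch,
            _identity_mapping(positions, rung_map), name="prop",
        )
        mutant = apply_design(scaffold_seq, design)
        for p in positions:
            assert mutant.letter_at(p) == mutant.letter_at(p + rung_map.offset)

    def test_rung2_partner_outside_sequence_errors(self, scaffold_seq, rung_map):
        # a scaffold truncated at 280 cannot host the rung-2 partner of 250
        from betagraft.structure_io import SequenceRecord

        truncated = SequenceRecord(
            id="truncated",
            sequence=scaffold_seq.sequence[: 280 - 218 + 1],
            start_number=218,
        )
        patch = _patch((250,), "W")
        mapping = SiteMapping(assignments=((250, 250),), rung_map=rung_map)
        with pytest.raises(ValueError, match="outside"):
            design_stacked_graft(
                truncated, rung_map, patch, mapping, name="oops"
            )


class TestValidateDesign:
    def test_symmetric_presets_validate_clean(self, scaffold_seq, rung_map):
        for name in ("alpha-SC6", "alpha-SC8", "alpha-SC9"):
            report = validate_design(load_preset(name), scaffold_seq, rung_map)
            assert report.clean, report.flags

    def test_sc3_anomaly_is_flagged(self, scaffold_seq, rung_map):
        """The verbatim α-SC3 list contains K269G, which breaks both the
        wild-type letter at 269 and the rung-pair symmetry; it must be
        reported, never corrected."""
        report = validate_design(load_preset("alpha-SC3"), scaffold_seq, rung_map)
        assert not report.clean
        assert any("K269G" in flag for flag in report.wt_mismatches)
        assert any("K269G" in flag for flag in report.asymmetries)

    def test_empty_design_is_clean(self, scaffold_seq, rung_map):
        from betagraft.graft_design import ConstructDesign

        empty = ConstructDesign(name="empty", scaffold_id="s", substitutions=())
        assert validate_design(empty, scaffold_seq, rung_map).clean
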