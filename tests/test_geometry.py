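import math

import numpy as np
import pytest

from ghmotif.errors import GHMotifError
from ghmotif.geometry import (
    RIGHT_HANDED_HELICAL,
    LEFT_HANDED_EXTENDED,
    LEFT_HANDED_HELICAL,
    RIGHT_HANDED_EXTENDED,
    TURN_TYPES,
    UNCLASSIFIED,
    active_site_distances,
    assign_beta_turns,
    backbone_torsions,
    classify_conformation,
    detect_hairpin,
    family_distance_summary,
    format_distance_table,
)
from ghmotif.io import FamilyConfig, ResidueRecord, StructureModel
from ghmotif.synthetic import (
    GeometrySpec,
    generate_peptide,
    hairpin_spec,
    strand_spec,
    type1_turn_spec,
)


class TestBackboneTorsions:
    def test_round_trip_ideal_strand(self):
        t = backbone_torsions(generate_peptide(strand_spec(6)))
        for i in range(1, 5):
            assert t.loc[i, "phi"] == pytest.approx(-120.0, abs=0.5)
            assert t.loc[i, "psi"] == pytest.approx(130.0, abs=0.5)

    def test_termini_undefined(self):
        t = backbone_torsions(generate_peptide(strand_spec(2)))
        assert math.isnan(t.loc[0, "phi"])
        assert math.isnan(t.loc[1, "psi"])

    def test_trans_omega_recovered(self):
        t = backbone_torsions(generate_peptide(strand_spec(5)))
        for i in range(1, 5):
            assert abs(abs(t.loc[i, "omega"]) - 180.0) < 0.5

    def test_random_chains_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            torsions = [
                (float(rng.uniform(-179, 179)), float(rng.uniform(-179, 179)), 180.0)
                for _ in range(10)
            ]
            s = generate_peptide(GeometrySpec(torsions=torsions))
            t = backbone_torsions(s)
            for i in range(1, 10):
                assert t.loc[i, "phi"] == pytest.approx(torsions[i][0], abs=0.5)
            for i in range(0, 9):
                assert t.loc[i, "psi"] == pytest.approx(torsions[i][1], abs=0.5)

    def test_chain_break_leaves_torsions_undefined(self):
        s = generate_peptide(strand_spec(6))
        shifted = []
        for k, r in enumerate(s.residues):
            atoms = {n: (xyz + 50.0 if k >= 3 else xyz) for n, xyz in r.atoms.items()}
            shifted.append(ResidueRecord(r.number, r.icode, r.name, atoms))
        broken = StructureModel("b", "A", shifted)
        t = backbone_torsions(broken)
        assert math.isnan(t.loc[3, "phi"])
        assert math.isnan(t.loc[2, "psi"])
        assert not math.isnan(t.loc[4, "phi"])

    def test_missing_backbone_atom_logged(self, caplog):
        s = generate_peptide(strand_spec(4))
        res = list(s.residues)
        atoms = dict(res[2].atoms)
        del atoms["CA"]
        res[2] = ResidueRecord(res[2].number, " ", res[2].name, atoms)
        with caplog.at_level("WARNING"):
            t = backbone_torsions(StructureModel("m", "A", res))
        assert math.isnan(t.loc[2, "phi"])
        assert any("missing backbone" in r.message for r in caplog.records)


class TestConformationClasses:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (57.0, 47.0, LEFT_HANDED_HELICAL),      # canonical alpha-L
            (-60.0, -45.0, RIGHT_HANDED_HELICAL),
            (75.0, 170.0, LEFT_HANDED_EXTENDED),
            (-120.0, 130.0, RIGHT_HANDED_EXTENDED),
            (10.0, 0.0, UNCLASSIFIED),              # near phi = 0 gap
            (60.0, -100.0, UNCLASSIFIED),
            (float("nan"), 30.0, UNCLASSIFIED),
        ],
    )
    def test_examples(self, phi, psi, expected):
        assert classify_conformation(phi, psi) == expected

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(1)
        mirror = {
            LEFT_HANDED_HELICAL: RIGHT_HANDED_HELICAL,
            LEFT_HANDED_EXTENDED: RIGHT_HANDED_EXTENDED,
            RIGHT_HANDED_HELICAL: LEFT_HANDED_HELICAL,
            RIGHT_HANDED_EXTENDED: LEFT_HANDED_EXTENDED,
            UNCLASSIFIED: UNCLASSIFIED,
        }
        for _ in range(200):
            phi = float(rng.uniform(-180, 180))
            psi = float(rng.uniform(-180, 180))
            assert classify_conformation(-phi, -psi) == \
                mirror[classify_conformation(phi, psi)]

    def test_left_handed_requires_positive_phi(self):
        for cls in (LEFT_HANDED_HELICAL, LEFT_HANDED_EXTENDED):
            rng = np.random.default_rng(2)
            for _ in range(100):
                phi = float(rng.uniform(-180, 20))
                psi = float(rng.uniform(-180, 180))
                assert classify_conformation(phi, psi) != cls


class TestBetaTurns:
    def test_canonical_type_i_detected(self):
        s = generate_peptide(type1_turn_spec())
        turns = {t.start_residue: t.turn_type for t in assign_beta_turns(s)}
        assert turns.get(2) == "I"

    def test_mirrored_dihedrals_give_type_i_prime(self):
        phi_e, psi_e = -120.0, 130.0
        torsions = [
            (phi_e, psi_e, 180.0), (phi_e, psi_e, 180.0),
            (60.0, 30.0, 180.0), (90.0, 0.0, 180.0),
            (phi_e, psi_e, 180.0), (phi_e, psi_e, 180.0),
        ]
        s = generate_peptide(GeometrySpec(torsions=torsions))
        turns = {t.start_residue: t.turn_type for t in assign_beta_turns(s)}
        assert turns.get(2) == "I'"

    def test_distance_gate(self):
        # extended chain has canonical-free dihedrals and CA(i)-CA(i+3) > 7
        s = generate_peptide(strand_spec(8))
        assert assign_beta_turns(s) == []

    def test_mirror_consistency_of_named_types(self):
        for name, canon in TURN_TYPES.items():
            mirrored = tuple(-a for a in canon)
            partner = {"I": "I'", "I'": "I", "II": "II'", "II'": "II"}[name]
            assert TURN_TYPES[partner] == pytest.approx(mirrored)

    def test_helical_interior_not_reported(self):
        s = generate_peptide(
            GeometrySpec(torsions=[(-60.0, -45.0, 180.0)] * 8)
        )
        turns = assign_beta_turns(s)
        assert all(t.turn_type != "I" for t in turns) and not turns


class TestHairpins:
    def test_canonical_4_4(self):
        s = generate_peptide(hairpin_spec(loop_length=4))
        hp = detect_hairpin(s, ((1, 4), (9, 12)))
        assert hp.label == "4:4"

    def test_tight_2_2(self):
        s = generate_peptide(hairpin_spec(loop_length=2))
        hp = detect_hairpin(s, ((1, 4), (7, 10)))
        assert hp.label == "2:2"

    def test_type_i_turn_inside_4_4_loop(self):
        s = generate_peptide(hairpin_spec(loop_length=4))
        turns = {t.start_residue: t.turn_type for t in assign_beta_turns(s)}
        assert turns.get(5) == "I"

    def test_parallel_strands_rejected(self):
        s = generate_peptide(strand_spec(12))
        with pytest.raises(GHMotifError):
            detect_hairpin(s, ((1, 4), (9, 12)))


def point_structure(spec: dict[int, tuple[str, dict[str, tuple]]]) -> StructureModel:
    residues = [
        ResidueRecord(num, " ", name, {a: np.array(xyz, float)
                                       for a, xyz in atoms.items()})
        for num, (name, atoms) in sorted(spec.items())
    ]
    return StructureModel("synthetic", "A", residues)


class TestActiveSiteDistances:
    def test_minimum_over_atom_sets(self):
        s = point_structure({
            1: ("GLU", {"OE1": (0, 0, 0), "OE2": (1, 0, 0)}),
            2: ("SER", {"OG": (4, 0, 0)}),
        })
        cfg = FamilyConfig("f", "xxxx", roles={"A": (1, "GLU"), "C": (2, "SER")})
        table = active_site_distances(s, cfg).set_index("pair")
        assert table.loc["A-C", "distance"] == pytest.approx(3.00)

    def test_missing_role_gives_nan(self):
        s = point_structure({1: ("GLU", {"OE1": (0, 0, 0)})})
        cfg = FamilyConfig("f", "xxxx", roles={"A": (1, "GLU")})
        table = active_site_distances(s, cfg).set_index("pair")
        assert math.isnan(table.loc["A-D", "distance"])

    def test_mutated_role_residue_skipped_with_log(self, caplog):
        s = point_structure({
            1: ("GLU", {"OE1": (0, 0, 0)}),
            2: ("ALA", {"CB": (3, 0, 0)}),
        })
        cfg = FamilyConfig("f", "xxxx", roles={"A": (1, "GLU"), "D": (2, "GLN")})
        with caplog.at_level("WARNING"):
            table = active_site_distances(s, cfg).set_index("pair")
        assert math.isnan(table.loc["A-D", "distance"])
        assert any("expected GLN" in r.message for r in caplog.records)

    def test_gln_uses_cb_only(self):
        s = point_structure({
            1: ("GLU", {"OE1": (0, 0, 0)}),
            2: ("GLN", {"CB": (5, 0, 0), "OE1": (1, 0, 0), "NE2": (1, 0, 0)}),
        })
        cfg = FamilyConfig("f", "xxxx", roles={"A": (1, "GLU"), "D": (2, "GLN")})
        table = active_site_distances(s, cfg).set_index("pair")
        assert table.loc["A-D", "distance"] == pytest.approx(5.00)

    def test_symmetry_and_triangle_inequality(self):
        s = point_structure({
            1: ("GLU", {"OE1": (0.0, 0.0, 0.0), "OE2": (1.2, 0.4, 0.0)}),
            2: ("ASP", {"OD1": (4.0, 1.0, 2.0), "OD2": (4.5, 0.0, 1.0)}),
            3: ("THR", {"OG1": (2.0, 3.0, 1.0)}),
        })
        roles = {"A": (1, "GLU"), "B": (2, "ASP"), "C": (3, "THR")}
        cfg = FamilyConfig("f", "xxxx", roles=roles)
        t = active_site_distances(s, cfg).set_index("pair")["distance"]
        assert t["A-C"] <= t["A-B"] + t["B-C"] + 0.02  # rounding slack
        assert t["A-B"] <= t["A-C"] + t["B-C"] + 0.02


class TestFamilySummary:
    def structure_with_ab(self, d):
        return point_structure({
            1: ("GLU", {"OE1": (0, 0, 0)}),
            2: ("ASP", {"OD1": (d, 0, 0)}),
        })

    def cfg(self):
        return FamilyConfig("f", "xxxx", roles={"A": (1, "GLU"), "B": (2, "ASP")})

    def test_singleton_family_sd_dash(self):
        summary = family_distance_summary([self.structure_with_ab(6.26)], [self.cfg()])
        row = summary.set_index("pair").loc["A-B"]
        assert row["mean"] == pytest.approx(6.26)
        assert math.isnan(row["sd"])
        fmt = format_distance_table(summary).set_index("pair")
        assert fmt.loc["A-B", "formatted"] == "6.26(–)"
        assert fmt.loc["A-C", "formatted"] == "/"

    def test_identical_structures_zero_sd(self):
        ss = [self.structure_with_ab(5.0)] * 2
        summary = family_distance_summary(ss, [self.cfg()] * 2).set_index("pair")
        assert summary.loc["A-B", "sd"] == pytest.approx(0.0)

    def test_population_sd_convention(self):
        ss = [self.structure_with_ab(d) for d in (4.0, 5.0, 6.0)]
        summary = family_distance_summary(ss, [self.cfg()] * 3).set_index("pair")
        assert summary.loc["A-B", "mean"] == pytest.approx(5.00)
        assert summary.loc["A-B", "sd"] == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-6)
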