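"""PDB parsing, structure-to-sequence mapping, and shell selection."""

import numpy as np
import pytest

from ancestlib.family import AlignedFamily, SequenceRecord
from ancestlib.asr import marginal_asr
from ancestlib.models import poisson_model
from ancestlib.phylo import PhyloTree
from ancestlib.simulate import ToyStructureSpec, make_toy_structure
from ancestlib.structure import (SelectionConfig, candidate_substitutions,
                                 map_structure_to_target, parse_structure,
                                 residues_within)

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       3.000   1.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.458   1.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


class TestParseStructure:
    def test_minimal_two_residues(self):
        s = parse_structure(MINI_PDB, "A")
        assert len(s.residues) == 2
        assert s.sequence == "AG"
        assert s.residues[0].coord("CA") == pytest.approx([1.458, 0, 0])

    def test_altloc_a_only(self):
        s = parse_structure(ALTLOC_PDB, "A")
        assert len(s.residues[0].atoms) == 1
        assert s.residues[0].coord("CA") == pytest.approx([0, 0, 0])

    def test_hetatm_and_other_chains_ignored(self):
        text = MINI_PDB.replace("END", "") + \
            "HETATM    5  O   HOH A   3      1.0     1.0     1.0\n" + \
            "ATOM      6  CA  TRP B   1       0.000   0.000   0.000" \
            "  1.00  0.00           C\nEND\n"
        s = parse_structure(text, "A")
        assert s.sequence == "AG"

    def test_missing_chain_raises(self):
        with pytest.raises(ValueError, match="chain 'Z'"):
            parse_structure(MINI_PDB, "Z")

    def test_malformed_line_reports_line_number(self):
        bad = MINI_PDB.replace(
            "ATOM      3  N   GLY A   2       3.000   1.000   0.000",
            "ATOM      3  N   GLY A   2       xxx")
        with pytest.raises(ValueError, match="line 3"):
            parse_structure(bad, "A")

    def test_toy_structure_round_trip(self, toy_helix):
        spec, pdb_text, _ = toy_helix
        s = parse_structure(pdb_text, spec.chain)
        assert len(s.residues) == 60
        assert s.sequence == spec.sequence

    def test_coordinates_agree_with_gemmi(self, toy_helix):
        gemmi = pytest.importorskip("gemmi")
        spec, pdb_text, _ = toy_helix
        mine = parse_structure(pdb_text, spec.chain)
        st = gemmi.read_pdb_string(pdb_text)
        chain = st[0][spec.chain]
        assert len(chain) == len(mine.residues)
        for g, m in zip(chain, mine.residues):
            ca = g["CA"][0].pos
            assert m.coord("CA") == pytest.approx([ca.x, ca.y, ca.z],
                                                  abs=1e-3)


class TestMapping:
    def test_identity_numbering(self, toy_helix):
        spec, pdb_text, _ = toy_helix
        s = parse_structure(pdb_text, spec.chain)
        target = SequenceRecord("t", spec.sequence)
        mapping = map_structure_to_target(s, target)
        assert set(mapping) == set(range(1, 61))
        assert all(mapping[i].number == i for i in mapping)

    def test_missing_n_terminus_reported_unmapped(self, toy_helix):
        spec, pdb_text, _ = toy_helix
        lines = [l for l in pdb_text.splitlines()
                 if not (l.startswith("ATOM") and int(l[22:26]) <= 2)]
        s = parse_structure("\n".join(lines), spec.chain)
        target = SequenceRecord("t", spec.sequence)
        mapping = map_structure_to_target(s, target)
        unmapped = set(range(1, 61)) - set(mapping)
        assert unmapped == {1, 2}
        assert mapping[3].one_letter == spec.sequence[2]

    def test_internal_deletion_mapped_by_alignment(self, toy_helix):
        spec, pdb_text, _ = toy_helix
        lines = [l for l in pdb_text.splitlines()
                 if not (l.startswith("ATOM") and 20 <= int(l[22:26]) <= 22)]
        s = parse_structure("\n".join(lines), spec.chain)
        mapping = map_structure_to_target(s, SequenceRecord("t",
                                                            spec.sequence))
        assert set(range(1, 61)) - set(mapping) == {20, 21, 22}
        # ground truth from the generator: residue numbers = positions
        assert all(mapping[p].number == p for p in mapping)

    def test_unrelated_structure_rejected(self, toy_helix):
        spec, pdb_text, _ = toy_helix
        s = parse_structure(pdb_text, spec.chain)
        with pytest.raises(ValueError, match="does not match"):
            map_structure_to_target(s, SequenceRecord("t", "W" * 60))


class TestResiduesWithin:
    def test_345_triangle_ca_mode(self):
        text = (
            "ATOM      1  CA  HIS A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.000   4.000   0.000"
            "  1.00  0.00           C\nEND\n")
        s = parse_structure(text, "A")
        mapping = {1: s.residues[0], 2: s.residues[1]}
        cfg = SelectionConfig(1, "H", 6.0, "CA")
        hits = residues_within(s, mapping, 1, cfg)
        assert hits == [(1, 0.0), (2, pytest.approx(5.0))]

    def test_anchor_mismatch_raises(self):
        s = parse_structure(MINI_PDB, "A")
        mapping = {1: s.residues[0]}
        with pytest.raises(ValueError, match="A1"):
            residues_within(s, mapping, 1, SelectionConfig(1, "H", 5.0, "CA"))

    def test_shell_equals_truth_matrix_threshold(self, toy_helix):
        """Selected set equals brute-force thresholding of the generator's
        ground-truth distance matrix."""
        spec, pdb_text, truth = toy_helix
        s = parse_structure(pdb_text, spec.chain)
        mapping = map_structure_to_target(s, SequenceRecord("t",
                                                            spec.sequence))
        anchor = spec.catalytic_position
        cfg = SelectionConfig(anchor, "H", 15.0, "CA")
        hits = residues_within(s, mapping, anchor, cfg)
        expected = {p + 1 for p in range(60)
                    if truth[anchor - 1, p] <= 15.0}
        assert {p for p, _ in hits} == expected
        for pos, dist in hits:
            assert dist == pytest.approx(truth[anchor - 1, pos - 1],
                                         abs=1e-6)

    @pytest.mark.parametrize("cut_small,cut_big", [(5, 10), (10, 15),
                                                   (3, 25)])
    def test_cutoff_monotonicity(self, toy_helix, cut_small, cut_big):
        spec, pdb_text, _ = toy_helix
        s = parse_structure(pdb_text, spec.chain)
        mapping = map_structure_to_target(s, SequenceRecord("t",
                                                            spec.sequence))
        anchor = spec.catalytic_position
        small = {p for p, _ in residues_within(
            s, mapping, anchor, SelectionConfig(anchor, "H", cut_small, "CA"))}
        big = {p for p, _ in residues_within(
            s, mapping, anchor, SelectionConfig(anchor, "H", cut_big, "CA"))}
        assert small <= big

    def test_min_heavy_atom_le_ca(self):
        def res(num, name3, coords):
            atom_lines = []
            for i, (an, (x, y, z)) in enumerate(coords.items()):
                atom_lines.append(
                    f"ATOM  {num * 10 + i:5d}  {an:<3s} {name3} A{num:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {an[0]:>2s}")
            return atom_lines
        lines = (res(1, "HIS", {"CA": (0, 0, 0), "CB": (1.5, 0, 0)})
                 + res(2, "ALA", {"CA": (8, 0, 0), "CB": (6.5, 0, 0)}))
        s = parse_structure("\n".join(lines) + "\nEND\n", "A")
        a, b = s.residues
        from ancestlib.structure import _residue_distance
        assert _residue_distance(a, b, "min_heavy_atom") <= \
            _residue_distance(a, b, "CA")
        assert _residue_distance(a, b, "min_heavy_atom") == pytest.approx(5.0)
        assert _residue_distance(a, b, "CA") == pytest.approx(8.0)


class TestCandidateSubstitutions:
    def _post_for(self, target, witness):
        """Family where two near-identical leaves witness the ancestor."""
        family = AlignedFamily(["t", "a", "b"], [target, witness, witness],
                               "t")
        tree = PhyloTree.from_newick("(t:0.8,a:0.001,b:0.001);")
        post = marginal_asr(family, tree, poisson_model())
        return family, post

    def test_identical_ancestor_gives_empty_set(self):
        family, post = self._post_for("KKKKKK", "KKKKKK")
        allowed = [(i, 0.0) for i in range(1, 7)]
        cs = candidate_substitutions(family, post, post.node_labels[0], "t",
                                     allowed)
        assert cs.n_substitutions == 0

    def test_constructed_seven_differences(self):
        target = "KKKKKKKKKKKK"
        witness = "RRRRRRRKKKKK"  # differs at positions 1-7
        family, post = self._post_for(target, witness)
        allowed = [(i, float(i)) for i in range(1, 13)]
        # the non-root internal node sits next to the witness pair
        node = post.node_labels[-1]
        cs = candidate_substitutions(family, post, node, "t", allowed)
        assert cs.n_substitutions == 7
        assert {e["position"] for e in cs.entries} == set(range(1, 8))
        assert all(e["wt"] == "K" and e["anc"] == "R" for e in cs.entries)

    def test_posterior_floor_filters(self):
        family, post = self._post_for("KKKK", "RRRR")
        node = post.node_labels[0]
        cfg = SelectionConfig(posterior_floor=1.01)
        cs = candidate_substitutions(family, post, node, "t",
                                     [(i, 0.0) for i in range(1, 5)], cfg)
        assert cs.n_substitutions == 0

    def test_unknown_node_raises(self):
        family, post = self._post_for("KKKK", "RRRR")
        with pytest.raises(ValueError, match="unknown"):
            candidate_substitutions(family, post, "N99", "t", [(1, 0.0)])
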