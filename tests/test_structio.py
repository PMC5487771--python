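import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gagmap.structio import (
    GlycanAnnotation,
    GlycanRing,
    PairEnergy,
    PairEnergyTable,
    ResidueKey,
    annotate_glycan,
    parse_decomp_table,
    parse_glycan_pattern,
    parse_structure_ensemble,
    subsample_tail,
    write_decomp_table,
    write_structure_ensemble,
)
from gagmap.synth import SynthSpec, gen_toy_complex_ensemble

TOY_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H   ALA A   1       0.000   1.000   0.000  1.00  0.00           H
ATOM      3  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      4  C1  SGN B   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      5  O3  SGN B   2       5.000   1.400   0.000  1.00  0.00           O
ATOM      6  C1  IDS B   3       9.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  H   ALA A   1       0.100   1.000   0.000  1.00  0.00           H
ATOM      3  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      4  C1  SGN B   2       5.100   0.000   0.000  1.00  0.00           C
ATOM      5  O3  SGN B   2       5.100   1.400   0.000  1.00  0.00           O
ATOM      6  C1  IDS B   3       9.100   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


class TestParseEnsemble:
    def test_models_share_topology(self, toy_pdb):
        ens = parse_structure_ensemble(toy_pdb, {"A"}, {"SGN", "IDS"})
        assert ens.n_frames == 2
        assert ens.n_atoms == 6
        assert len(ens.protein_residues()) == 1
        assert len(ens.glycan_residues()) == 2
        # the hydrogen got attached to N by covalent distance
        n_atom = ens.residues[0].atoms[0]
        assert n_atom.name == "N" and n_atom.bonded_hydrogens == [2]

    def test_no_glycan_match_errors(self, toy_pdb):
        with pytest.raises(ValueError, match="no glycan"):
            parse_structure_ensemble(toy_pdb, {"A", "B"}, {"XYZ"})

    def test_unassignable_residue_errors(self, toy_pdb):
        with pytest.raises(ValueError, match="neither"):
            parse_structure_ensemble(toy_pdb, {"A"}, {"SGN"})  # IDS unclaimed

    def test_inconsistent_model_errors(self, tmp_path):
        # drop the last atom from model 2 only
        lines = TOY_PDB.splitlines(keepends=True)
        body = "".join(lines[:-3] + lines[-2:])  # remove last ATOM of model 2
        path = tmp_path / "broken.pdb"
        path.write_text(body)
        with pytest.raises(ValueError, match="model"):
            parse_structure_ensemble(path, {"A"}, {"SGN", "IDS"})

    def test_write_parse_round_trip_pdb_precision(self, tmp_path):
        toy = gen_toy_complex_ensemble(SynthSpec(seed=3, n_frames=10))
        out = tmp_path / "rt.pdb"
        write_structure_ensemble(toy.ensemble, out)
        back = parse_structure_ensemble(
            out, {"A"}, {r.key.resname for r in toy.ensemble.glycan_residues()}
        )
        assert back.n_frames == toy.ensemble.n_frames
        assert np.allclose(back.frames, toy.ensemble.frames, atol=1e-3)


class TestGlycanPattern:
    @pytest.mark.parametrize(
        "token,ring_type,flags",
        [
            ("GlcNS", "GlcNS", {"NS"}),
            ("GlcNS6S", "GlcNS", {"NS", "6S"}),
            ("GlcN", "GlcN", set()),
            ("IdoA", "IdoA", set()),
            ("IdoA2S", "IdoA2S", {"2S"}),
        ],
    )
    def test_token_decoding(self, token, ring_type, flags):
        assert parse_glycan_pattern(token) == [(ring_type, frozenset(flags))]

    def test_dp6_derivative_without_idoa_sulfates(self, toy_pdb):
        # fully desulfated iduronic acids: no IdoA2S rings anywhere
        pattern = "GlcNS6S-IdoA-GlcNS6S-IdoA-GlcNS6S-IdoA"
        rings = parse_glycan_pattern(pattern)
        assert all(rt != "IdoA2S" for rt, _ in rings)

    def test_annotation_indices_and_length_check(self, toy_pdb):
        ens = parse_structure_ensemble(toy_pdb, {"A"}, {"SGN", "IDS"})
        ann = annotate_glycan(ens, "GlcNS6S-IdoA2S")
        assert [r.ring_index for r in ann.rings] == [1, 2]
        assert ann.rings[0].key.resname == "SGN"
        with pytest.raises(ValueError, match="rings"):
            annotate_glycan(ens, "GlcNS6S")

    def test_fully_sulfated_dp5_alternation(self, tmp_path):
        toy = gen_toy_complex_ensemble(
            SynthSpec(seed=0, n_frames=2,
                      glycan_pattern="GlcNS6S-IdoA2S-GlcNS6S-IdoA2S-GlcNS6S",
                      planted_hbond_pairs=[], planted_hot_pairs=[])
        )
        types = [r.ring_type for r in toy.annotation.rings]
        assert types == ["GlcNS", "IdoA2S", "GlcNS", "IdoA2S", "GlcNS"]
        assert [r.ring_index for r in toy.annotation.rings] == [1, 2, 3, 4, 5]

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["GlcN", "IdoA"]),
                st.booleans(),  # N-sulfate (GlcN) / 2-O-sulfate (IdoA)
                st.booleans(),  # 6-O-sulfate
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_pattern_round_trip(self, rings):
        tokens = []
        for base, s1, s6 in rings:
            t = base
            if base == "GlcN" and s1:
                t += "S"
            if base == "IdoA" and s1:
                t += "2S"
            if s6:
                t += "6S"
            tokens.append(t)
        pattern = "-".join(tokens)
        decoded = parse_glycan_pattern(pattern)
        ann = GlycanAnnotation(
            rings=[
                GlycanRing(
                    key=ResidueKey("B", 100 + i, "UNK", "glycan"),
                    ring_type=rt, sulfation=fl, ring_index=i + 1,
                )
                for i, (rt, fl) in enumerate(decoded)
            ]
        )
        assert parse_glycan_pattern(ann.pattern()) == decoded


class TestSubsampleTail:
    def test_contract_100_of_last_500(self):
        toy = gen_toy_complex_ensemble(SynthSpec(seed=0, n_frames=1000,
                                                 planted_hbond_pairs=[],
                                                 planted_hot_pairs=[]))
        sub = subsample_tail(toy.ensemble, 500, 100)
        assert sub.n_frames == 100
        # evenly spaced within the tail window, endpoints included
        matches = [
            np.flatnonzero((toy.ensemble.frames == f).all(axis=(1, 2)))[0]
            for f in sub.frames
        ]
        assert matches[0] == 500 and matches[-1] == 999
        assert all(b > a for a, b in zip(matches, matches[1:]))

    def test_identity_when_count_equals_tail(self, toy_complex):
        sub = subsample_tail(toy_complex.ensemble, 10, 10)
        assert np.array_equal(sub.frames, toy_complex.ensemble.frames[-10:])

    def test_even_spacing_small_window(self, toy_complex):
        # tail of 10 frames, 3 picks -> first, middle, last of the window
        n = toy_complex.ensemble.n_frames
        sub = subsample_tail(toy_complex.ensemble, 10, 3)
        expected = [n - 10, n - 10 + 4, n - 1]  # rint(linspace(0, 9, 3)) = 0, 4, 9
        got = [
            int(np.flatnonzero((toy_complex.ensemble.frames == f).all(axis=(1, 2)))[0])
            for f in sub.frames
        ]
        assert got == expected

    def test_count_exceeding_tail_errors(self, toy_complex):
        with pytest.raises(ValueError, match="count"):
            subsample_tail(toy_complex.ensemble, 5, 6)


AMBER_CSV = """\
Resid 1,Resid 2,Internal,van der Waals,Electrostatic,Polar Solvation,TOTAL
LYS 118,HE 201,0.0,-1.2,-18.3,6.8,-12.7
LYS 113,HE 201,0.0,-0.9,-13.1,5.0,-9.0
LYS 128,HE 201,0.0,-0.8,-11.4,4.5,-7.7
LYS 112,HE 201,0.0,-0.7,-10.0,3.5,-7.2
ARG 122,HE 201,0.0,-0.9,-9.8,3.5,-7.2
GLN 127,HE 201,0.0,-1.1,-8.0,2.7,-6.4
ASN 18,HE 201,0.0,-0.8,-6.3,2.5,-4.6
ALA 129,HE 201,0.0,-0.6,-3.9,1.3,-3.2
ARG 35,HE 201,0.0,-0.1,-2.4,1.3,-1.2
LYS 9,HE 201,0.0,-0.1,-2.2,1.2,-1.1
"""


class TestDecompTables:
    def test_amber_csv_top_contributor(self, tmp_path):
        # per-residue totals shaped like a published top-10 decomposition:
        # the strongest binder residue is Lys 118 at -12.7 kcal/mol
        path = tmp_path / "decomp.csv"
        path.write_text(AMBER_CSV)
        table = parse_decomp_table(path, dialect="amber_csv")
        (top_key, top_val), *_ = table.top_contributors(1)
        assert top_key.resname == "LYS" and top_key.resnum == 118
        assert top_val == pytest.approx(-12.7, abs=1e-9)

    def test_amber_csv_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Resid 1,Resid 2,van der Waals\nLYS 1,HE 2,-1.0\n")
        with pytest.raises(ValueError, match="Electrostatic"):
            parse_decomp_table(path, dialect="amber_csv")

    def test_duplicate_pair_errors(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(AMBER_CSV + "LYS 118,HE 201,0.0,-1.2,-18.3,6.8,-12.7\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_decomp_table(path, dialect="amber_csv")

    def test_empty_table_is_valid(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_decomp_table(PairEnergyTable(entries={}), path)
        table = parse_decomp_table(path, dialect="canonical_tsv")
        assert table.entries == {}

    def test_canonical_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        entries = {}
        for i in range(1, 6):
            for j in (1, 2):
                key = ResidueKey("A", i, "LYS", "protein")
                entries[(key, j)] = PairEnergy(
                    vdw=float(rng.normal()), ele_vac=float(rng.normal()),
                    ele_rf=float(rng.normal()), hbond_fraction=float(rng.random()),
                )
        table = PairEnergyTable(entries=entries, provenance="ingested", n_frames_averaged=7)
        path = tmp_path / "rt.tsv"
        write_decomp_table(table, path)
        back = parse_decomp_table(path, dialect="canonical_tsv")
        assert back.n_frames_averaged == 7
        assert set(back.entries) == set(entries)
        for k, e in entries.items():
            assert back.entries[k].vdw == pytest.approx(e.vdw, abs=1e-6)
            assert back.entries[k].ele_vac == pytest.approx(e.ele_vac, abs=1e-6)
            assert back.entries[k].ele_rf == pytest.approx(e.ele_rf, abs=1e-6)
            assert back.entries[k].ele_total == pytest.approx(e.ele_total, abs=1e-6)

    def test_ele_total_always_recomputed(self):
        e = PairEnergy(vdw=-1.0, ele_vac=-3.0, ele_rf=1.0)
        assert e.ele_total == pytest.approx(-2.0, abs=1e-12)
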