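import json

import numpy as np
import pandas as pd
import pytest

from foldscreen.model import ComplexModel, ConfidenceBundle, attach
from foldscreen.model_io import (
    read_confidence,
    read_network,
    read_score_table,
    read_structure,
    write_network,
    write_score_table,
    write_structure,
)
from foldscreen.synthetic_data import SyntheticSpec, make_dimer

from conftest import make_pae_pair


class TestStructureIO:
    def test_pdb_round_trip_preserves_coordinates_and_plddt(self, tmp_path):
        model, _ = make_dimer(SyntheticSpec(seed=3))
        path = tmp_path / "dimer.pdb"
        write_structure(model, path)
        back = read_structure(path, format="pdb")
        assert back.chain_ids == model.chain_ids
        for ca, cb in zip(model.chains, back.chains):
            assert ca.sequence == cb.sequence
            for ra, rb in zip(ca.residues, cb.residues):
                # PDB precision is 1e-3 Å for coordinates, 1e-2 for B-factor
                np.testing.assert_allclose(ra.coords(), rb.coords(),
                                           atol=1.5e-3)
                assert rb.plddt == pytest.approx(ra.plddt, abs=0.01)

    def test_b_factor_column_becomes_plddt(self, tmp_path):
        model, _ = make_dimer(SyntheticSpec(seed=3))
        for chain in model.chains:
            for res in chain.residues:
                res.plddt = 90.0
        path = tmp_path / "b90.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert all(r.plddt == pytest.approx(90.0, abs=0.01)
                   for c in back.chains for r in c.residues)

    def test_hetatm_only_file_is_an_empty_model_error(self, tmp_path):
        path = tmp_path / "waters.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1      10.000  10.000  10.000"
            "  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no protein residues"):
            read_structure(path)

    def test_unparsable_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(path, format="mmcif")


class TestConfidenceIO:
    def test_colabfold_pae_maps_directly(self, tmp_path):
        path = tmp_path / "scores.json"
        path.write_text(json.dumps(
            {"pae": [[0, 5], [6, 0]], "ptm": 0.5, "iptm": 0.4}))
        bundle = read_confidence(path, dialect="colabfold")
        assert bundle.pae.shape == (2, 2)
        assert bundle.pae[0, 1] == 5.0
        assert bundle.ptm == 0.5 and bundle.iptm == 0.4

    def test_af3_ligand_tokens_are_dropped(self, tmp_path):
        # 3 protein residues + 1 ligand token interleaved; hand-enumerated
        # survivors are tokens 0, 1, 3 → 3×3 matrix
        pae = [
            [0, 1, 9, 2],
            [1, 0, 9, 3],
            [9, 9, 0, 9],
            [2, 3, 9, 0],
        ]
        path = tmp_path / "af3.json"
        path.write_text(json.dumps({
            "pae": pae,
            "token_chain_ids": ["A", "A", "A", "B"],
            "token_res_ids": [1, 2, 3, 1],
            "token_res_names": ["ALA", "GLY", "LIG", "SER"],
        }))
        bundle = read_confidence(path, dialect="af3_server")
        assert bundle.n_residues == 3
        assert bundle.residue_chain == [("A", 1), ("A", 2), ("B", 1)]
        np.testing.assert_array_equal(
            bundle.pae, [[0, 1, 2], [1, 0, 3], [2, 3, 0]])

    def test_af3_per_atom_tokens_reduce_to_one_per_residue(self, tmp_path):
        # two atoms of the same residue → keep the first token
        pae = [[0, 2, 4], [2, 0, 4], [4, 4, 0]]
        path = tmp_path / "af3b.json"
        path.write_text(json.dumps({
            "pae": pae,
            "token_chain_ids": ["A", "A", "B"],
            "token_res_ids": [1, 1, 1],
        }))
        bundle = read_confidence(path)
        assert bundle.n_residues == 2
        assert bundle.pae[0, 1] == 4.0

    def test_missing_pae_key_is_a_dialect_error(self, tmp_path):
        path = tmp_path / "nopae.json"
        path.write_text(json.dumps({"plddt": [90.0]}))
        with pytest.raises(ValueError, match="no PAE"):
            read_confidence(path)

    def test_dialect_equivalence_same_content_same_bundle(self, tmp_path):
        rng = np.random.default_rng(5)
        pae = rng.uniform(0, 20, (4, 4)).round(3)
        np.fill_diagonal(pae, 0.0)
        cf = tmp_path / "cf.json"
        cf.write_text(json.dumps({"pae": pae.tolist(),
                                  "ptm": 0.8, "iptm": 0.7}))
        af3 = tmp_path / "af3.json"
        af3.write_text(json.dumps({
            "pae": pae.tolist(),
            "token_chain_ids": ["A", "A", "B", "B"],
            "token_res_ids": [1, 2, 1, 2],
            "ptm": 0.8, "iptm": 0.7,
        }))
        b1 = read_confidence(cf)
        b2 = read_confidence(af3)
        np.testing.assert_array_equal(b1.pae, b2.pae)
        assert b1.ptm == b2.ptm and b1.iptm == b2.iptm

    def test_pae_above_cap_rejected_as_corrupt(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"pae": [[0, 50], [50, 0]]}))
        with pytest.raises(ValueError, match="outside"):
            read_confidence(path)


class TestAttach:
    def test_count_match_and_mismatch(self, rng):
        pair = make_pae_pair(10, 12, rng)
        assert pair.pae.shape == (22, 22)
        model = pair.model
        short = ConfidenceBundle(
            pae=np.zeros((21, 21)),
            residue_chain=[("A", i + 1) for i in range(21)])
        with pytest.raises(ValueError, match="21"):
            attach(model, short)

    def test_swapped_chain_order_permutes_pae(self, rng):
        pair = make_pae_pair(2, 2, rng)
        model = pair.model
        # bundle listing chain B first, with a hand-built 4×4 PAE
        pae = np.array([
            [0.0, 1.0, 2.0, 3.0],
            [4.0, 0.0, 5.0, 6.0],
            [7.0, 8.0, 0.0, 9.0],
            [10.0, 11.0, 12.0, 0.0],
        ])
        swapped = ConfidenceBundle(
            pae=pae,
            residue_chain=[("B", 1), ("B", 2), ("A", 1), ("A", 2)])
        re = attach(model, swapped)
        # hand-derived permutation: model order A1,A2,B1,B2 → rows 2,3,0,1
        expected = pae[np.ix_([2, 3, 0, 1], [2, 3, 0, 1])]
        np.testing.assert_array_equal(re.pae, expected)
        assert re.pae[0, 2] == pae[2, 0]


class TestTablesAndNetworks:
    def test_score_table_round_trip(self, tmp_path):
        df = pd.DataFrame([
            {"bait": "b1", "candidate": "c1", "method": "af2m",
             "model_id": "m1", "weighted": 0.5, "pdockq": 0.3,
             "decision": "retain", "exclusion_reason": ""},
            {"bait": "b2", "candidate": "c2", "method": "af3",
             "model_id": "m2", "weighted": 0.2, "pdockq": 0.1,
             "decision": "exclude", "exclusion_reason": "weighted ≤ 0.40"},
            {"bait": "b3", "candidate": "c3", "method": "apd2",
             "model_id": "m3", "weighted": 0.9, "pdockq": 0.8,
             "decision": "retain", "exclusion_reason": ""},
        ])
        path = tmp_path / "table.tsv"
        write_score_table(df, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 4  # header + 3 records
        back = read_score_table(path)
        assert list(back.bait) == ["b1", "b2", "b3"]
        np.testing.assert_allclose(back.weighted, df.weighted)

    def test_empty_table_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_score_table(pd.DataFrame(), tmp_path / "empty.tsv")

    def test_network_graphml_round_trip(self, tmp_path):
        import networkx as nx
        g = nx.Graph()
        g.add_node("m1", weighted=0.9, method="af3")
        g.add_node("m2", weighted=0.7, method="af2m")
        g.add_edge("m1", "m2", interface_lddt=0.9)
        path = tmp_path / "net.graphml"
        write_network(g, path)
        back = read_network(path)
        assert set(back.nodes) == {"m1", "m2"}
        assert back["m1"]["m2"]["interface_lddt"] == pytest.approx(0.9)
        assert back.nodes["m1"]["weighted"] == pytest.approx(0.9)
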