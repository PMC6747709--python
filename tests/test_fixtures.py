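"""Synthetic-data generators and packaged reference tables."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from nbmature.fixtures import (PlantedScenario, gen_coding_dna, gen_score_table,
                               gen_toy_complex, load_reference_tables)
from nbmature.rmhdp import interface_residues, scan_hotspot_motifs
from nbmature.rounds import fold_from_ddg
from nbmature.structio import parse_variant, translate

from .conftest import oracle_motif_hits


class TestToyComplex:
    def test_contact_contract(self):
        contacts = [55, 58, 107, 108, 109, 110]
        s = gen_toy_complex(120, contacts, seed=0)
        assert interface_residues(s, "A", "B").sorted() == contacts

    def test_noncontacts_beyond_8A(self):
        s = gen_toy_complex(30, [10], seed=1)
        wide = interface_residues(s, "A", "B", cutoff=8.0)
        assert wide.sorted() == [10]

    def test_empty_contacts(self):
        s = gen_toy_complex(10, [], seed=0)
        assert len(interface_residues(s, "A", "B")) == 0

    def test_same_seed_identical_coordinates(self):
        a = gen_toy_complex(15, [3, 9], seed=4)
        b = gen_toy_complex(15, [3, 9], seed=4)
        for ca, cb in zip(a.chains, b.chains):
            for ra, rb in zip(ca.residues, cb.residues):
                for at_a, at_b in zip(ra.atoms, rb.atoms):
                    np.testing.assert_array_equal(at_a.xyz, at_b.xyz)

    def test_out_of_range_contact_rejected(self):
        with pytest.raises(ValueError):
            gen_toy_complex(10, [11], seed=0)

    def test_pdb_written(self, tmp_path):
        path = tmp_path / "toy.pdb"
        gen_toy_complex(8, [2], seed=0, pdb_path=path)
        assert path.read_text().startswith("ATOM")


class TestCodingDna:
    def test_serine_hotspot_planted_as_agy(self):
        cs, manifest = gen_coding_dna("MSK", [2], seed=0)
        assert cs.codon(1) in ("AGC", "AGT")
        covered = {r for h in scan_hotspot_motifs(cs) for r in h.covered_residues}
        assert 2 in covered
        assert manifest["requested"] == [2]

    def test_translation_preserved(self):
        protein = "MSKVAGTSFLW"
        cs, _ = gen_coding_dna(protein, [2, 9], seed=3)
        assert translate(cs) == protein

    def test_isolated_tryptophan_infeasible(self):
        # W is TGG; with no neighbours there is no way to overlap AGY/RGYW
        with pytest.raises(ValueError, match="cannot plant"):
            gen_coding_dna("W", [1], seed=0)

    def test_manifest_matches_scanner(self):
        rng = np.random.default_rng(13)
        aa = list("ARNDQEGHILKMFSTWYV")
        protein = list("M" + "".join(rng.choice(aa, size=119)))
        # plant at residues with motif-compatible codons: S (AGY), and V/A
        # preceded by a K codon ending in A/G (boundary-spanning RGYW)
        protein[19] = "S"
        protein[38], protein[39] = "K", "V"
        protein[58], protein[59] = "K", "A"
        protein = "".join(protein)
        hotspots = [20, 40, 60]
        cs, manifest = gen_coding_dna(protein, hotspots, seed=13)
        covered = {r for h in scan_hotspot_motifs(cs) for r in h.covered_residues}
        assert sorted(covered) == manifest["covered"]
        assert set(hotspots) <= covered

    def test_manifest_independent_of_scan_module(self):
        cs, manifest = gen_coding_dna("MSSK", [2, 3], seed=0)
        # recompute coverage from the naive substring oracle
        dna = cs.nucleotides
        covered = set()
        for name, start in oracle_motif_hits(dna):
            k = 3 if name == "AGY" else 4
            for i in range(len(dna) // 3):
                if 3 * i < start + k and start < 3 * i + 3:
                    covered.add(i + 1)
        assert sorted(covered) == manifest["covered"]

    def test_deterministic_under_seed(self):
        a, _ = gen_coding_dna("MSKVAGTSF", [2], seed=7)
        b, _ = gen_coding_dna("MSKVAGTSF", [2], seed=7)
        assert a.nucleotides == b.nucleotides


class TestScoreTable:
    def test_zero_noise_single_plant_gives_10_fold(self):
        scenario = PlantedScenario(
            seed=0, planted_effects={"S109V": -1.364},
            scorers=(("s1", 0.0, 1.0, 0.0),))
        table = gen_score_table([parse_variant("S109V"), parse_variant("S55A")],
                                scenario)
        ddg = table.loc["S109V", "s1"] - table.loc["WT", "s1"]
        assert fold_from_ddg(ddg) == pytest.approx(10.0, abs=0.01)

    def test_additive_multi_point(self):
        scenario = PlantedScenario(
            seed=0, planted_effects={"G107W": -1.0, "T108H": -0.5},
            scorers=(("s1", 0.0, 2.0, 0.0),))
        table = gen_score_table(
            [parse_variant("G107W+T108H")], scenario)
        assert (table.loc["G107W+T108H", "s1"] - table.loc["WT", "s1"]
                == pytest.approx(2.0 * -1.5))

    def test_epistasis_hook(self):
        scenario = PlantedScenario(
            seed=0, planted_effects={"G107W": -1.0, "T108H": -0.5},
            epistasis={frozenset({"G107W", "T108H"}): +0.8},
            scorers=(("s1", 0.0, 1.0, 0.0),))
        assert scenario.true_ddg(parse_variant("G107W+T108H")) == pytest.approx(-0.7)

    def test_same_seed_identical(self):
        scenario = PlantedScenario.default_campaign(seed=2)
        vs = [parse_variant(l) for l in ("G107W", "S55A")]
        pd.testing.assert_frame_equal(gen_score_table(vs, scenario),
                                      gen_score_table(vs, scenario))

    def test_pure_noise_rank_uncorrelated_with_labels(self):
        from nbmature.consensus import consensus_z

        labels = [f"G{i}W" for i in range(1, 41)]
        corrs = []
        for seed in range(20):
            scenario = PlantedScenario.zero_signal(seed=seed)
            table = gen_score_table([parse_variant(l) for l in labels], scenario,
                                    include_wt=False)
            ranked = consensus_z(table).ranked
            order = [int(lab[1:-1]) for lab in ranked.index]
            corrs.append(np.corrcoef(order, np.arange(len(order)))[0, 1])
        assert abs(np.mean(corrs)) < 0.15


class TestReferenceTables:
    def test_interface_and_hotspot_sizes(self, reference_tables):
        assert len(reference_tables.interface) == 19  # 10 single + 105..113
        assert len(reference_tables.hotspot) == 11

    def test_negative_z_cell_count_is_50(self, reference_tables):
        z = reference_tables.consensus_z
        assert len(z) == 50
        assert (z["z"] < 0).all()

    def test_round1_singles_present(self, reference_tables):
        z = reference_tables.consensus_z
        labels = {f"{r.wt}{r.position}{r.mut}" for r in z.itertuples()}
        assert {"S55Q", "G107I", "G107W", "T108H",
                "S109E", "S109V", "F110A", "V58D"} <= labels

    def test_kd_table_fold(self, reference_tables):
        kd = reference_tables.kd_tm["kd_nM"]
        assert kd["M0"] / kd["M7"] == pytest.approx(87.4, abs=0.05)

    def test_reference_z(self, reference_tables):
        assert reference_tables.reference_z == -0.20

    def test_checksum_guard(self, tmp_path, monkeypatch):
        import nbmature.fixtures as fx

        real = {"table1_sites.tsv": "tampered\n"}

        def fake_read(name):
            if name == "checksums.json":
                return json.dumps(
                    {"table1_sites.tsv": hashlib.sha256(b"other").hexdigest()})
            return real.get(name, "")

        monkeypatch.setattr(fx, "_read_packaged", fake_read)
        with pytest.raises(ValueError, match="checksum mismatch"):
            fx.load_reference_tables()
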