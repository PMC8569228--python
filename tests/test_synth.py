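"""Synthetic dataset generator: planted motifs, divergence, decoys."""

import dataclasses

import pytest

from evasinclass.motifs import cys6_motif, cys8_motif, scan
from evasinclass.synth import (SyntheticConfig, evolve_lineages,
                               generate_dataset, plant_motif)


class TestPlantMotif:
    def test_minimal_length_forces_minimal_spacings(self):
        seq, anchors = plant_motif(29, cys6_motif(), seed=5)
        assert anchors == (1, 5, 12, 16, 18, 29)
        assert len(scan(seq, cys6_motif())) == 1

    def test_too_short_error_names_minimum(self):
        with pytest.raises(ValueError, match="29"):
            plant_motif(20, cys6_motif(), seed=0)

    @pytest.mark.parametrize("motif,length", [("cys6", 33), ("cys6", 90),
                                              ("cys8", 69), ("cys8", 90)])
    def test_planted_sequence_scans_positive_exactly_once(self, motif, length, rng):
        m = cys6_motif() if motif == "cys6" else cys8_motif()
        for _ in range(10):
            seq, anchors = plant_motif(length, m, rng)
            hits = scan(seq, m)
            assert len(hits) == 1
            assert hits[0].anchors == anchors
            assert seq.count("C") == m.n_anchors  # anchors are the only Cys


class TestEvolveLineages:
    def test_zero_within_rate_gives_identical_members(self):
        cfg = SyntheticConfig(n_class1=6, n_class2=4,
                              substitution_rate_within=0.0)
        members = evolve_lineages(cfg)
        l1 = {m["sequence"] for m in members if m["lineage"] == 1}
        l2 = {m["sequence"] for m in members if m["lineage"] == 2}
        assert len(l1) == 1 and len(l2) == 1

    def test_anchors_never_mutated(self):
        cfg = SyntheticConfig(n_class1=20, n_class2=0, motif_class1="cys8",
                              substitution_rate_within=0.3,
                              substitution_rate_between=0.5, seed=3)
        for m in evolve_lineages(cfg):
            for pos in m["anchors"]:
                assert m["sequence"][pos - 1] == "C"

    def test_none_motif_class_has_cysteine_deficit(self):
        cfg = SyntheticConfig(seed=11)  # class 2 defaults to no motif
        for m in evolve_lineages(cfg):
            if m["motif"] == "none":
                assert m["sequence"].count("C") < 6

    def test_invalid_rate_ordering_rejected(self):
        with pytest.raises(ValueError, match="recoverab"):
            SyntheticConfig(substitution_rate_within=0.5,
                            substitution_rate_between=0.4).validate()


class TestGenerateDataset:
    def test_counts_match_config(self, tmp_path):
        cfg = SyntheticConfig(n_class1=5, n_class2=5, n_decoy_no_signal=1,
                              n_decoy_stop=1, n_decoy_unrelated=1, seed=2)
        paths = generate_dataset(cfg, tmp_path / "d")
        fasta = paths["fasta"].read_text()
        assert fasta.count(">") == 13
        truth = paths["truth"].read_text().strip().splitlines()
        assert len(truth) == 14  # header + 13 rows

    def test_stop_decoys_carry_stop_in_mature_region(self, tmp_path):
        cfg = SyntheticConfig(n_class1=4, n_class2=4, n_decoy_stop=2, seed=7)
        paths = generate_dataset(cfg, tmp_path / "d")
        seqs = {}
        for block in paths["fasta"].read_text().split(">")[1:]:
            header, seq = block.split("\n", 1)
            seqs[header.split()[0]] = seq.strip()
        n_stop = sum("*" in s[cfg.signal_length:] for s in seqs.values())
        assert n_stop == 2
        # stops never land in the signal peptide
        assert all("*" not in s[:cfg.signal_length] for s in seqs.values())

    def test_no_signal_decoys_missing_from_cleavage_table(self, tmp_path):
        cfg = SyntheticConfig(n_class1=3, n_class2=3, n_decoy_no_signal=2, seed=1)
        paths = generate_dataset(cfg, tmp_path / "d")
        truth_rows = [r.split("\t") for r in
                      paths["truth"].read_text().strip().splitlines()[1:]]
        no_signal = {r[0] for r in truth_rows if r[-1] == "no_signal"}
        assert len(no_signal) == 2
        cleav_ids = {r.split("\t")[0] for r in
                     paths["cleavage"].read_text().strip().splitlines()[1:]}
        assert cleav_ids.isdisjoint(no_signal)
        assert cleav_ids == {r[0] for r in truth_rows if r[-1] != "no_signal"}

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=42)
        p1 = generate_dataset(cfg, tmp_path / "a")
        p2 = generate_dataset(dataclasses.replace(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_planted_motifs_detected_in_mature_bodies(self, tmp_path):
        cfg = SyntheticConfig(n_class1=6, n_class2=6, motif_class1="cys8",
                              motif_class2="cys6", seed=9)
        paths = generate_dataset(cfg, tmp_path / "d")
        motifs = {"cys6": cys6_motif(), "cys8": cys8_motif()}
        truth = {r.split("\t")[0]: r.split("\t") for r in
                 paths["truth"].read_text().strip().splitlines()[1:]}
        for block in paths["fasta"].read_text().split(">")[1:]:
            header, seq = block.split("\n", 1)
            rid = header.split()[0]
            row = truth[rid]
            if row[6] == "" and row[4] in motifs:  # non-decoy with a motif
                mature = seq.strip()[cfg.signal_length:]
                assert scan(mature, motifs[row[4]])
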