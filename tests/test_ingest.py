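"""FASTA ingest, mature-protein derivation and record filtering."""

import pytest

from evasinclass.ingest import (HeuristicCleavageProvider, ProteinRecord,
                                TableCleavageProvider, derive_mature,
                                filter_records, locate_protein_start,
                                read_fasta)
from evasinclass.synth import SyntheticConfig, generate_dataset


def make_record(seq, rid="r1", **kw):
    return ProteinRecord(id=rid, raw_sequence=seq, **kw)


class TestReadFasta:
    def test_order_and_metadata(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">X1 genus=Ixodes species=ricinus\nMKVA\n"
                     ">X2\nacde\n>X3 genus=Hyalomma\nMMM\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["X1", "X2", "X3"]
        assert (recs[0].genus, recs[0].species) == ("Ixodes", "ricinus")
        assert recs[1].raw_sequence == "ACDE"  # upper-cased

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_malformed_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACDE\n>X1\nMKV\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(p)

    def test_duplicate_ids_listed(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">A\nMK\n>B\nMK\n>A\nMV\n")
        with pytest.raises(ValueError, match="A"):
            read_fasta(p)


class TestProteinStart:
    @pytest.mark.parametrize("seq,start", [("GGMKLM", 3), ("MKV", 1)])
    def test_first_met_rule(self, seq, start):
        rec = locate_protein_start(make_record(seq))
        assert rec.protein_start == start
        assert rec.status == "ok"

    def test_no_met_flagged(self):
        rec = locate_protein_start(make_record("KKVV"))
        assert rec.status == "no_met"
        assert rec.protein_start is None


class TestDeriveMature:
    def test_table_contract(self):
        seq = "M" + "L" * 19 + "CDEFG"
        rec = locate_protein_start(make_record(seq))
        derive_mature(rec, TableCleavageProvider({"r1": 21}))
        assert rec.mature_start == 21
        assert rec.mature_sequence == "CDEFG"

    def test_absent_from_table_means_no_signal(self):
        rec = locate_protein_start(make_record("M" + "L" * 25))
        derive_mature(rec, TableCleavageProvider({}))
        assert rec.status == "no_signal"

    def test_out_of_range_position_raises(self):
        rec = locate_protein_start(make_record("MKVLL"))
        with pytest.raises(ValueError, match="cleavage position"):
            derive_mature(rec, TableCleavageProvider({"r1": 99}))

    def test_heuristic_matches_truth_on_synthetic_records(self, tmp_path):
        """Generator signal model and heuristic provider agree exactly."""
        cfg = SyntheticConfig(n_class1=50, n_class2=50, n_decoy_no_signal=5,
                              n_decoy_stop=0, n_decoy_unrelated=0, seed=31)
        paths = generate_dataset(cfg, tmp_path / "d")
        truth = {}
        for row in paths["truth"].read_text().strip().splitlines()[1:]:
            f = row.split("\t")
            truth[f[0]] = (f[3], f[6])
        provider = HeuristicCleavageProvider(window=cfg.signal_length)
        n_checked = 0
        for rec in read_fasta(paths["fasta"]):
            locate_protein_start(rec)
            derive_mature(rec, provider)
            cleavage, decoy = truth[rec.id]
            if decoy == "no_signal":
                assert rec.status == "no_signal"
            else:
                assert rec.mature_start == int(cleavage)
                n_checked += 1
        assert n_checked == 100


class TestFilters:
    def _processed(self, seq, table, rid="r1"):
        rec = locate_protein_start(make_record(seq, rid))
        return derive_mature(rec, TableCleavageProvider(table))

    def test_internal_stop_dropped(self):
        rec = self._processed("M" + "L" * 19 + "ACD*EF", {"r1": 21})
        kept, dropped = filter_records([rec])
        assert kept == [] and dropped[0][1] == "internal_stop"

    def test_stop_before_mature_start_is_tolerated(self):
        rec = self._processed("M*" + "L" * 19 + "ACDEF", {"r1": 22})
        kept, dropped = filter_records([rec])
        assert len(kept) == 1 and dropped == []

    def test_no_signal_dropped(self):
        rec = self._processed("M" + "L" * 25, {})
        kept, dropped = filter_records([rec])
        assert dropped[0][1] == "no_signal"

    def test_partition_and_idempotence(self, tmp_path):
        cfg = SyntheticConfig(n_class1=5, n_class2=5, n_decoy_no_signal=1,
                              n_decoy_stop=1, n_decoy_unrelated=1, seed=13)
        paths = generate_dataset(cfg, tmp_path / "d")
        provider = TableCleavageProvider(str(paths["cleavage"]))
        records = read_fasta(paths["fasta"])
        for rec in records:
            locate_protein_start(rec)
            derive_mature(rec, provider)
        kept, dropped = filter_records(records)
        assert len(kept) + len(dropped) == len(records)
        # the unrelated decoy has a signal peptide: it falls to the screen,
        # not to these filters
        assert len(kept) == 11
        reasons = sorted(r for _, r in dropped)
        assert reasons == ["internal_stop", "no_signal"]
        kept2, dropped2 = filter_records(kept)
        assert kept2 == kept and dropped2 == []
        for rec in kept:
            assert "*" not in rec.mature_sequence
            assert rec.mature_start > rec.protein_start
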