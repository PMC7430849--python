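import numpy as np
import pytest

import squigalign as sq
from squigalign.model_io import FormatError, read_eventalign_tsv


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">r1\nACGTAC\n")
        recs = sq.read_fasta(p)
        assert len(recs) == 1
        assert recs[0].read_id == "r1" and recs[0].sequence == "ACGTAC"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert sq.read_fasta(p) == []

    def test_three_entries_in_order(self, tmp_path):
        p = tmp_path / "three.fa"
        p.write_text(">a\nAC\nGT\n>b\nTTTT\n>c\nGGGG\n")
        recs = sq.read_fasta(p)
        assert [r.read_id for r in recs] == ["a", "b", "c"]
        assert recs[0].sequence == "ACGT"  # multi-line sequences joined

    def test_case_and_rna_normalised(self, tmp_path):
        p = tmp_path / "rna.fa"
        p.write_text(">r\nacgu\n")
        assert sq.read_fasta(p)[0].sequence == "ACGT"

    def test_empty_sequence_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\nACGT\n>b\n>c\nGG\n")
        with pytest.raises(FormatError, match="line 3"):
            sq.read_fasta(p)

    def test_data_before_header_names_line(self, tmp_path):
        p = tmp_path / "bad2.fa"
        p.write_text("ACGT\n>r\nAC\n")
        with pytest.raises(FormatError, match="line 1"):
            sq.read_fasta(p)


class TestReadPoreModel:
    def test_full_6mer_table(self, tmp_path, m6):
        p = tmp_path / "model.tsv"
        lines = ["kmer\tlevel_mean\tlevel_stdv"]
        for r in range(4096):
            lines.append(
                f"{sq.rank_to_kmer(r, 6)}\t{m6.level_mean[r]:.5f}\t{m6.level_stdv[r]:.5f}"
            )
        p.write_text("\n".join(lines) + "\n")
        model = sq.read_pore_model(p)
        assert model.k == 6 and model.n_defined() == 4096
        np.testing.assert_allclose(model.level_mean, m6.level_mean, atol=1e-5)

    def test_toy_2mer_table_no_header(self, tmp_path):
        p = tmp_path / "toy.tsv"
        rows = [f"{sq.rank_to_kmer(r, 2)}\t{90 + r}\t1.5" for r in range(16)]
        p.write_text("\n".join(rows) + "\n")
        model = sq.read_pore_model(p)
        assert model.k == 2
        assert model.mean(sq.kmer_rank("AC")) == pytest.approx(91.0)

    def test_duplicate_kmer_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("AAAAAA\t90\t1\nAAAAAA\t91\t1\n")
        with pytest.raises(FormatError, match="duplicate"):
            sq.read_pore_model(p)

    def test_mixed_lengths_rejected(self, tmp_path):
        p = tmp_path / "mixed.tsv"
        p.write_text("AA\t90\t1\nAAA\t91\t1\n")
        with pytest.raises(FormatError, match="mixed"):
            sq.read_pore_model(p)

    def test_nonpositive_stdv_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("AA\t90\t0\n")
        with pytest.raises(FormatError, match="stdv"):
            sq.read_pore_model(p)


class TestReadSignalTsv:
    def test_one_sample_per_line(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("\n".join(f"{100 + i}.5" for i in range(10)) + "\n")
        rec = sq.read_signal_tsv(p)
        assert rec.raw.size == 10
        assert rec.sample_rate == 4000.0
        assert rec.raw[3] == pytest.approx(103.5)

    def test_sample_rate_header(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("#sample_rate=3012\n100.0\n101.0\n")
        assert sq.read_signal_tsv(p).sample_rate == 3012.0

    def test_two_column_form(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("0\t100.0\n1\t101.5\n")
        np.testing.assert_allclose(sq.read_signal_tsv(p).raw, [100.0, 101.5])

    def test_error_names_line(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("100\n101\n102\nabc\n104\n")
        with pytest.raises(FormatError, match="line 4"):
            sq.read_signal_tsv(p)


class TestEventsTsv:
    def test_roundtrip(self, tmp_path, m6):
        seq = sq.random_sequence(100, seed=13)
        events, _ = sq.simulate_events(seq, m6, sq.ScalingParams(), sq.SimParams(seed=13))
        p = tmp_path / "events.tsv"
        sq.write_events_tsv(events, p)
        back = sq.read_events_tsv(p)
        assert len(back) == len(events)
        assert [e.start for e in back] == [e.start for e in events]
        np.testing.assert_allclose(
            [e.mean for e in back], [e.mean for e in events], rtol=1e-5
        )


class TestEventalignTsv:
    def _aligned_read(self, m6, seed=14):
        seq = sq.random_sequence(80, seed=seed)
        events, _ = sq.simulate_events(seq, m6, sq.ScalingParams(), sq.SimParams(seed=seed))
        ranks = sq.seq_to_kmer_ranks(seq, 6)
        scaling = sq.estimate_scalings(events, ranks, m6)
        alignment = sq.abea_align(events, seq, m6, scaling, W=100)
        read = sq.ReadRecord(read_id="r1", sequence=seq, events=events)
        return alignment, read, scaling

    def test_empty_alignment_header_only(self, tmp_path, m6):
        _, read, scaling = self._aligned_read(m6)
        empty = sq.EventAlignment(pairs=[], score=float("-inf"), n_kmers=75)
        p = tmp_path / "ea.tsv"
        sq.write_eventalign_tsv(empty, read, m6, scaling, p)
        assert p.read_text().strip() == "\t".join(
            ["read_id", "kmer_idx", "kmer", "event_idx",
             "event_mean", "scaled_model_mean", "log_emission"]
        )

    def test_row_per_pair_roundtrip(self, tmp_path, m6):
        alignment, read, scaling = self._aligned_read(m6)
        assert len(alignment.pairs) > 3
        p = tmp_path / "ea.tsv"
        sq.write_eventalign_tsv(alignment, read, m6, scaling, p)
        df = read_eventalign_tsv(p)
        assert len(df) == len(alignment.pairs)
        assert list(zip(df.event_idx, df.kmer_idx)) == alignment.pairs
        np.testing.assert_allclose(
            df.event_mean, [read.events[e].mean for e, _ in alignment.pairs], rtol=1e-5
        )
        # kmer column decodes back to the sequence k-mer
        assert all(
            km == read.sequence[q : q + 6] for km, q in zip(df.kmer, df.kmer_idx)
        )

    def test_out_of_range_pair_rejected(self, tmp_path, m6):
        alignment, read, scaling = self._aligned_read(m6)
        alignment.pairs[0] = (10**6, 0)
        with pytest.raises(ValueError, match="out of range"):
            sq.write_eventalign_tsv(alignment, read, m6, scaling, tmp_path / "x.tsv")
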