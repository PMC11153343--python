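"""PSI equations, junction frequencies, and transcript consequence calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nebfish import splicing as sp
from nebfish import synthetic as syn
from nebfish.splicing import (ExonCountRecord, JunctionLocus, SpliceEvent,
                              TranscriptModel)


def record(ir, er, length=100, read_length=101):
    return ExonCountRecord(exon_id="e", exon_index=1, exon_length=length,
                           read_length=read_length, inclusion_reads=ir,
                           exclusion_reads=er)


class TestPSI:
    def test_worked_example(self):
        """IR=90, ER=20, L=100, r=101: IRn=0.45, ERn=0.20, PSI=69.23%."""
        p = sp.psi(record(90, 20))
        assert p.ir_norm == pytest.approx(0.45)
        assert p.er_norm == pytest.approx(0.20)
        assert p.psi == pytest.approx(100 * 0.45 / 0.65)

    def test_boundary_laws(self):
        assert sp.psi(record(0, 37)).psi == 0.0
        assert sp.psi(record(52, 0)).psi == 100.0

    def test_zero_coverage_undefined(self):
        assert sp.psi(record(0, 0)).psi is None

    def test_read_length_below_two_rejected(self):
        with pytest.raises(ValueError):
            record(1, 1, read_length=1)

    @settings(derandomize=True, max_examples=100)
    @given(ir=st.integers(1, 10_000), er=st.integers(1, 10_000),
           k=st.integers(2, 50))
    def test_scale_invariance_and_monotonicity(self, ir, er, k):
        base = sp.psi(record(ir, er)).psi
        scaled = sp.psi(record(ir * k, er * k)).psi
        assert scaled == pytest.approx(base, abs=1e-9)
        assert sp.psi(record(ir + 1, er)).psi > base


class TestEventFrequencies:
    def test_even_split(self):
        locus = JunctionLocus("l", 50, (("alt", 5, 50),), 0)
        freqs = {f.label: f.frequency for f in sp.event_frequencies(locus)}
        assert freqs["canonical"] == 50.0 and freqs["alt"] == 50.0

    def test_retention_dominated_locus(self):
        """An 18.7/5.4/75.9% acceptor-site/retention mixture, as seen at a
        splice-acceptor mutation with near-total loss of the canonical site."""
        locus = JunctionLocus("l", 0, (("alt_34", 34, 18_700), ("alt_3", 3, 5_400)),
                              75_900)
        freqs = {f.label: f.frequency for f in sp.event_frequencies(locus)}
        assert freqs["alt_34"] == pytest.approx(18.7)
        assert freqs["alt_3"] == pytest.approx(5.4)
        assert freqs["intron_retention"] == pytest.approx(75.9)
        assert freqs["canonical"] == 0.0

    def test_single_category_is_100(self):
        locus = JunctionLocus("l", 0, (), 17)
        assert sp.event_frequencies(locus)[-1].frequency == 100.0

    def test_zero_locus_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            sp.event_frequencies(JunctionLocus("l", 0, (), 0))

    @settings(derandomize=True, max_examples=100)
    @given(c=st.integers(0, 10**6), a=st.integers(0, 10**6),
           r=st.integers(0, 10**6))
    def test_frequencies_sum_to_100(self, c, a, r):
        if c + a + r == 0:
            return
        locus = JunctionLocus("l", c, (("alt", 1, a),), r)
        total = sum(f.frequency for f in sp.event_frequencies(locus))
        assert total == pytest.approx(100.0, abs=1e-9)


class TestApplySpliceEvent:
    def test_canonical_length_is_exon_sum(self, crafted_transcript):
        assert len(crafted_transcript.canonical_mrna()) == 21

    def test_donor_shift_lengthens_mrna(self, crafted_transcript):
        ev = SpliceEvent("donor_shift", 1, +5)
        assert len(sp.apply_splice_event(crafted_transcript, ev)) == 26

    def test_retention_inserts_full_intron(self):
        tm = syn.generate_toy_transcript([120, 90, 150], [96, 60], seed=0)
        mrna = sp.apply_splice_event(tm, SpliceEvent("intron_retention", 1))
        assert len(mrna) == 360 + 96

    def test_exon_skip_removes_exon(self, crafted_transcript):
        mrna = sp.apply_splice_event(crafted_transcript, SpliceEvent("exon_skip", 2))
        assert len(mrna) == 21 - 9

    def test_zero_delta_shift_disallowed(self):
        with pytest.raises(ValueError):
            SpliceEvent("donor_shift", 1, 0)

    def test_shift_beyond_intron_rejected(self, crafted_transcript):
        with pytest.raises(ValueError, match="intron"):
            sp.apply_splice_event(crafted_transcript,
                                  SpliceEvent("donor_shift", 1, +50))


class TestClassifyConsequence:
    def test_plus5_frameshift_with_ptc_in_exon2(self, crafted_transcript):
        call = sp.classify_consequence(crafted_transcript,
                                       SpliceEvent("donor_shift", 1, +5))
        assert call.frame_status == "frameshift"
        assert call.ptc and call.ptc_exon_index == 2

    def test_minus18_in_frame(self):
        tm = syn.generate_toy_transcript([30, 60, 30], [40, 40], seed=6)
        call = sp.classify_consequence(tm, SpliceEvent("donor_shift", 2, -18))
        assert call.frame_status == "in_frame"

    @pytest.mark.parametrize("delta,expected", [(34, "frameshift"), (3, "in_frame")])
    def test_acceptor_shift_frame(self, delta, expected):
        tm = syn.generate_toy_transcript([120, 90, 150], [96, 60], seed=4)
        call = sp.classify_consequence(tm, SpliceEvent("acceptor_shift", 2, delta))
        assert call.frame_status == expected

    def test_retention_with_in_frame_stops(self, crafted_transcript):
        """Intron 2 (TAATAG) carries two in-frame stops; retaining it is
        in-frame but introduces both, the first mapped to the upstream exon."""
        call = sp.classify_consequence(crafted_transcript,
                                       SpliceEvent("intron_retention", 2))
        assert call.frame_status == "in_frame"
        assert call.ptc and call.n_stops_introduced == 2
        assert call.ptc_exon_index == 2

    def test_frameshift_without_stop_flagged(self):
        # every codon downstream of a +1 shift is sense by construction here
        tm = TranscriptModel(sequence="ATGGGT" + "GTCAG" + "GGAGGAGGATAA",
                             exons=((1, 6), (12, 23)))
        call = sp.classify_consequence(tm, SpliceEvent("donor_shift", 1, +1))
        assert call.frame_status == "frameshift"
        assert not call.ptc and call.no_stop_found

    @settings(derandomize=True, max_examples=60)
    @given(delta=st.integers(-20, 30).filter(lambda d: d != 0))
    def test_frame_rule_is_delta_mod_3(self, delta):
        tm = syn.generate_toy_transcript([60, 90, 60], [40, 40], seed=17)
        call = sp.classify_consequence(tm, SpliceEvent("acceptor_shift", 1, delta))
        assert (call.frame_status == "in_frame") == (delta % 3 == 0)


class TestRoundTripsAndIO:
    def test_mixture_recovery_at_depth(self):
        """Simulated locus frequencies recover the generating mixture."""
        n = 10_000
        spec = syn.SpliceSimSpec(total_junction_reads=n, seed=13)
        _, locus = syn.simulate_junction_counts(spec)
        freqs = {f.label: f.frequency for f in sp.event_frequencies(locus)}
        for label, p in spec.event_frequencies.items():
            if label == "canonical":
                label_out = "canonical"
            elif label == "intron_retention":
                label_out = "intron_retention"
            else:
                label_out = label
            sd_pct = 100.0 * np.sqrt(p * (1 - p) / n)
            assert freqs[label_out] == pytest.approx(100 * p, abs=3 * sd_pct + 1e-9)

    def test_transcript_fasta_gff_round_trip(self, tmp_path, crafted_transcript):
        fa, gff = tmp_path / "t.fa", tmp_path / "t.gff3"
        sp.write_transcript(crafted_transcript, fa, gff)
        back = sp.read_transcript(fa, gff)
        assert back.sequence == crafted_transcript.sequence
        assert back.exons == crafted_transcript.exons
        assert back.canonical_mrna() == crafted_transcript.canonical_mrna()

    def test_counts_and_junction_tsv_round_trip(self, tmp_path):
        spec = syn.SpliceSimSpec(seed=2)
        records, locus = syn.simulate_junction_counts(spec)
        syn.write_counts_tsv(records, tmp_path / "c.tsv")
        syn.write_junction_tsv(locus, tmp_path / "j.tsv")
        back = sp.read_exon_counts_tsv(tmp_path / "c.tsv")
        assert [(r.inclusion_reads, r.exclusion_reads) for r in back] == \
               [(r.inclusion_reads, r.exclusion_reads) for r in records]
        locus_back = sp.read_junction_tsv(tmp_path / "j.tsv")
        assert locus_back.total_reads == locus.total_reads
        assert locus_back.canonical_reads == locus.canonical_reads

    def test_minus_strand_mrna_is_revcomp(self, crafted_transcript):
        tm = crafted_transcript
        n = len(tm.sequence)
        rc = tm.sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        minus = TranscriptModel(sequence=rc,
                                exons=tuple(sorted((n - e + 1, n - s + 1)
                                                   for s, e in tm.exons)),
                                strand="-")
        assert minus.canonical_mrna() == tm.canonical_mrna()
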