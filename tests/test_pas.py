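import numpy as np
import pandas as pd
import pytest
from intervaltree import Interval, IntervalTree

from polterm.annotation import GeneModel, GenomeSequence, TranscriptModel, reverse_complement
from polterm.pas import (
    OligoARun,
    PasWindow,
    SignalHit,
    annotate_windows,
    build_windows,
    call_regulated_pas,
    count_window_reads,
    scan_oligoA,
    scan_signals,
    summarize_gene,
)


def _genome(seq, chrom="chr1"):
    return GenomeSequence({chrom: seq})


class TestScanSignals:
    def test_planted_plus_strand_hit(self):
        hits = scan_signals(_genome("GGAATAAACC"))
        assert hits == [SignalHit("chr1", "+", 2, 8, "AATAAA")]

    def test_planted_minus_strand_hit(self):
        hits = scan_signals(_genome("GGTTTATTCC"))
        assert hits == [SignalHit("chr1", "-", 2, 8, "AATAAA")]

    def test_overlapping_hits_both_found(self):
        hits = scan_signals(_genome("AATAAATAAA"))
        plus = {(h.start, h.end) for h in hits if h.strand == "+"}
        assert {(0, 6), (4, 10)} <= plus

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            scan_signals(_genome("ACGTX"))

    def test_matches_sliding_window_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 4000))
        hits = scan_signals(_genome(seq))
        expected = set()
        for i in range(len(seq) - 5):
            hexamer = seq[i : i + 6]
            for motif in ("AATAAA", "ATTAAA"):
                if hexamer == motif:
                    expected.add(("+", i, motif))
                if hexamer == reverse_complement(motif):
                    expected.add(("-", i, motif))
        assert {(h.strand, h.start, h.motif) for h in hits} == expected


class TestScanOligoA:
    def test_planted_run(self):
        runs = scan_oligoA(_genome("CC" + "A" * 12 + "GG"))
        assert runs == [OligoARun("chr1", "+", 2, 14)]

    def test_nine_as_below_threshold(self):
        assert scan_oligoA(_genome("G" + "A" * 9 + "G")) == []

    def test_t_run_is_minus_strand(self):
        runs = scan_oligoA(_genome("CC" + "T" * 11 + "GG"))
        assert runs == [OligoARun("chr1", "-", 2, 13)]

    def test_matches_maximal_run_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000, p=[0.55, 0.15, 0.15, 0.15]))
        runs = scan_oligoA(_genome(seq), min_run=5)
        expected = []
        i = 0
        while i < len(seq):
            if seq[i] == "A":
                j = i
                while j < len(seq) and seq[j] == "A":
                    j += 1
                if j - i >= 5:
                    expected.append(("+", i, j))
                i = j
            else:
                i += 1
        got = [(r.strand, r.start, r.end) for r in runs if r.strand == "+"]
        assert got == expected


class TestBuildWindows:
    CL = {"chr1": 20_000}

    def test_plus_strand_signal_window_geometry(self):
        w = build_windows([SignalHit("chr1", "+", 1000, 1006, "AATAAA")], [], self.CL)
        assert (w[0].start, w[0].end) == (700, 1056)

    def test_minus_strand_signal_window_geometry(self):
        w = build_windows([SignalHit("chr1", "-", 1000, 1006, "AATAAA")], [], self.CL)
        assert (w[0].start, w[0].end) == (950, 1306)

    def test_nearby_signals_merge(self):
        hits = [
            SignalHit("chr1", "+", 1000, 1006, "AATAAA"),
            SignalHit("chr1", "+", 1100, 1106, "ATTAAA"),
        ]
        w = build_windows(hits, [], self.CL)
        assert len(w) == 1
        assert (w[0].start, w[0].end) == (700, 1156)
        assert len(w[0].members) == 2

    def test_signal_window_overlapping_oligoa_removed(self):
        hits = [SignalHit("chr1", "+", 1000, 1006, "AATAAA")]
        runs = [OligoARun("chr1", "+", 1020, 1032)]
        w = build_windows(hits, runs, self.CL)
        assert all(x.kind == "oligoA" for x in w)

    def test_oligoa_on_other_strand_does_not_remove(self):
        hits = [SignalHit("chr1", "+", 1000, 1006, "AATAAA")]
        runs = [OligoARun("chr1", "-", 1020, 1032)]
        w = build_windows(hits, runs, self.CL)
        assert any(x.kind == "signal" for x in w)

    def test_windows_clipped_to_chromosome(self):
        w = build_windows([SignalHit("chr1", "+", 100, 106, "AATAAA")], [], self.CL)
        assert w[0].start == 0

    def test_idempotent_on_own_output(self):
        hits = [
            SignalHit("chr1", "+", 1000, 1006, "AATAAA"),
            SignalHit("chr1", "+", 1100, 1106, "AATAAA"),
            SignalHit("chr1", "-", 5000, 5006, "ATTAAA"),
        ]
        first = build_windows(hits, [], self.CL)
        again = build_windows(
            [SignalHit(w.chrom, w.strand, w.start, w.end, "AATAAA") for w in first],
            [], self.CL, up=0, down=0,
        )
        assert [(w.chrom, w.strand, w.start, w.end) for w in again] == [
            (w.chrom, w.strand, w.start, w.end) for w in first
        ]

    def _oracle(self, hits, runs, clen):
        """Independent interval-algebra oracle via intervaltree merge."""
        out = {}
        for strand in "+-":
            sig = IntervalTree()
            for h in hits:
                if h.strand != strand:
                    continue
                s, e = (h.start - 300, h.end + 50) if strand == "+" else (h.start - 50, h.end + 300)
                sig.add(Interval(max(0, s), min(clen, e)))
            oa = IntervalTree()
            for r in runs:
                if r.strand != strand:
                    continue
                s, e = (r.start - 350, r.end) if strand == "+" else (r.start, r.end + 350)
                oa.add(Interval(max(0, s), min(clen, e)))
            sig.merge_overlaps(strict=True)
            oa.merge_overlaps(strict=True)
            surviving = sorted(
                (iv.begin, iv.end) for iv in sig if not oa.overlap(iv.begin, iv.end)
            )
            out[strand] = {
                "signal": surviving,
                "oligoA": sorted((iv.begin, iv.end) for iv in oa),
            }
        return out

    def test_random_sequences_match_interval_oracle(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 20_000, p=[0.4, 0.1, 0.1, 0.4]))
            genome = _genome(seq)
            hits, runs = scan_signals(genome), scan_oligoA(genome, min_run=6)
            windows = build_windows(hits, runs, {"chr1": 20_000})
            oracle = self._oracle(hits, runs, 20_000)
            for strand in "+-":
                for kind in ("signal", "oligoA"):
                    got = sorted(
                        (w.start, w.end) for w in windows
                        if w.strand == strand and w.kind == kind
                    )
                    assert got == oracle[strand][kind], (strand, kind)
            # post-merge disjointness within (kind, strand)
            for strand in "+-":
                for kind in ("signal", "oligoA"):
                    ivs = sorted((w.start, w.end) for w in windows
                                 if w.strand == strand and w.kind == kind)
                    assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))
            assert all(0 <= w.start < w.end <= 20_000 for w in windows)

    def test_strand_mirror_symmetry(self, rng):
        G = 10_000
        seq = "".join(rng.choice(list("ACGT"), G, p=[0.4, 0.1, 0.1, 0.4]))
        mirror = reverse_complement(seq)

        def _windows(s):
            g = _genome(s)
            return build_windows(scan_signals(g), scan_oligoA(g, min_run=6), {"chr1": G})

        flip = {"+": "-", "-": "+"}
        got = {(w.strand, w.start, w.end, w.kind) for w in _windows(seq)}
        mirrored = {
            (flip[w.strand], G - w.end, G - w.start, w.kind) for w in _windows(mirror)
        }
        assert got == mirrored


class TestAnnotateWindows:
    def _gene(self):
        t = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand="+",
            span_start=1_000, span_end=9_000,
            exons=[(1_000, 2_000), (4_000, 5_000), (8_000, 9_000)],
            utr3=[(8_700, 9_000)],
        )
        return GeneModel("g", [t], representative="t")

    def test_preference_order(self):
        wins = [
            PasWindow("chr1", "+", 8_750, 8_800, "signal"),   # utr3
            PasWindow("chr1", "+", 4_900, 5_100, "signal"),   # exon + intron -> exon
            PasWindow("chr1", "+", 2_500, 2_600, "signal"),   # intron
            PasWindow("chr1", "+", 15_000, 15_100, "signal"),  # intergenic
            PasWindow("chr1", "-", 4_500, 4_600, "signal"),   # wrong strand
        ]
        annotate_windows(wins, [self._gene()])
        assert [w.location for w in wins] == [
            "utr3", "exon", "intron", "intergenic", "intergenic",
        ]

    def test_matches_overlap_oracle(self, rng):
        gene = self._gene()
        t = gene.transcripts[0]
        wins = []
        for _ in range(100):
            s = int(rng.integers(0, 19_000))
            wins.append(PasWindow("chr1", "+", s, s + int(rng.integers(20, 400)), "signal"))
        annotate_windows(wins, [gene])

        def oracle(w):
            def hit(ivs):
                return any(w.start < e and s < w.end for s, e in ivs)

            if hit(t.utr3):
                return "utr3"
            if hit(t.exons):
                return "exon"
            if hit(t.introns()):
                return "intron"
            return "intergenic"

        assert [w.location for w in wins] == [oracle(w) for w in wins]


class TestCountWindowReads:
    def test_sense_reads_counted(self):
        w = [PasWindow("chr1", "+", 100, 200, "signal")]
        reads = {"s1": [("chr1", 120, 170, "+")] * 7}
        counts = count_window_reads(w, reads)
        assert counts.iloc[0, 0] == 7

    def test_antisense_read_not_counted(self):
        w = [PasWindow("chr1", "+", 100, 200, "signal")]
        counts = count_window_reads(w, {"s1": [("chr1", 120, 170, "-")]})
        assert counts.iloc[0, 0] == 0

    def test_unstranded_read_errors(self):
        w = [PasWindow("chr1", "+", 100, 200, "signal")]
        with pytest.raises(ValueError, match="unstranded"):
            count_window_reads(w, {"s1": [("chr1", 120, 170, ".")]})

    def test_matches_interval_overlap_oracle(self, rng):
        wins = []
        for _ in range(20):
            s = int(rng.integers(0, 9_500))
            wins.append(PasWindow("chr1", "+" if rng.random() < 0.5 else "-",
                                  s, s + int(rng.integers(50, 400)), "signal"))
        reads = []
        for _ in range(500):
            s = int(rng.integers(0, 9_900))
            reads.append(("chr1", s, s + 50, "+" if rng.random() < 0.5 else "-"))
        counts = count_window_reads(wins, {"s1": reads})
        for i, w in enumerate(wins):
            oracle = sum(
                1 for c, s, e, st in reads
                if st == w.strand and s < w.end and w.start < e
            )
            assert counts.iloc[i, 0] == oracle


class TestCallAndSummarize:
    def _win(self, start, end, reg="non", loc="exon", strand="+"):
        w = PasWindow("chr1", strand, start, end, "signal", location=loc)
        w.regulation = reg
        return w

    def test_regulation_calls(self):
        wins = [
            PasWindow("chr1", "+", 0, 100, "signal"),
            PasWindow("chr1", "+", 200, 300, "signal"),
            PasWindow("chr1", "+", 400, 500, "signal"),
            PasWindow("chr1", "+", 600, 700, "signal"),
        ]
        de = pd.DataFrame(
            {"log2fc": [-2.0, 0.9, 1.5, np.nan], "padj": [1e-6, 0.2, 1e-4, np.nan]},
            index=[w.window_id for w in wins],
        )
        call_regulated_pas(wins, de)
        assert [w.regulation for w in wins] == ["down", "non", "up", "untested"]

    def test_missing_window_left_untested_and_stray_id_errors(self):
        wins = [PasWindow("chr1", "+", 0, 100, "signal")]
        call_regulated_pas(wins, pd.DataFrame(columns=["log2fc", "padj"]))
        assert wins[0].regulation == "untested"
        stray = pd.DataFrame({"log2fc": [1.0], "padj": [0.5]}, index=["nope"])
        with pytest.raises(ValueError, match="unknown window ids"):
            call_regulated_pas(wins, stray)

    def test_down_utr3_with_upstream_up(self):
        wins = [
            self._win(9_000, 9_300, "down", "utr3"),
            self._win(4_000, 4_300, "up", "intron"),
        ]
        s = summarize_gene("g", wins, "shortened")
        assert s.category == "down"
        assert s.has_down_utr3_pas and s.has_upstream_up_pas
        assert s.n_upstream_up == 1

    def test_minus_strand_upstream_is_genomically_right(self):
        wins = [
            self._win(1_000, 1_300, "down", "utr3", strand="-"),
            self._win(5_000, 5_300, "up", "intron", strand="-"),
            self._win(200, 500, "up", "exon", strand="-"),  # 3' of the UTR window
        ]
        s = summarize_gene("g", wins, "shortened")
        assert s.n_upstream_up == 1

    def test_only_non_regulated_windows(self):
        s = summarize_gene("g", [self._win(0, 100, "non")], "unaffected")
        assert s.category == "non" and not s.has_down_utr3_pas

    def test_no_tested_windows(self):
        s = summarize_gene("g", [self._win(0, 100, "untested")], "unaffected")
        assert s.category == "untested"
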