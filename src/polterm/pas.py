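"""Poly(A)-site windows from genomic signal scans and 3'end counting.

Canonical poly(A) signal hexamers (AATAAA, ATTAAA) and oligo-A runs of
at least 10 consecutive As (internal-priming decoys) are located on
both strands of the genome.  Strand-oriented counting windows are built
around them: signal windows run from 300 bp upstream of the signal to
50 bp downstream (to include the actual cleavage site); oligo-A windows
from 350 bp upstream of the run to its end.  Overlapping windows are
merged within each kind, and signal windows overlapping an oligo-A
window on the same strand are removed, excluding internally primed
positions from counting.  Remaining windows are annotated by gene
feature (3'UTR > exon > intron > intergenic), counted against stranded
3'end reads, called down-/up-/non-regulated from a differential table,
and summarized per gene.

"Upstream" is always in transcription (strand) direction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomeSequence, reverse_complement

SIGNAL_MOTIFS = ("AATAAA", "ATTAAA")
SIGNAL_UP = 300
SIGNAL_DOWN = 50
OLIGOA_UP = 350
OLIGOA_MIN_RUN = 10

_VALID_SEQ_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class SignalHit:
    chrom: str
    strand: str
    start: int
    end: int
    motif: str


@dataclass(frozen=True)
class OligoARun:
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PasWindow:
    chrom: str
    strand: str
    start: int
    end: int
    kind: str  # 'signal' | 'oligoA'
    members: list = field(default_factory=list)
    location: str | None = None  # utr3 | exon | intron | intergenic
    gene_id: str | None = None
    regulation: str = "untested"

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


def _check_sequence(seq: str, chrom: str) -> None:
    if not _VALID_SEQ_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"{chrom}: non-ACGTN characters {bad}")


def _find_all(seq: str, motif: str) -> Iterable[int]:
    i = seq.find(motif)
    while i != -1:
        yield i
        i = seq.find(motif, i + 1)


def scan_signals(
    genome: GenomeSequence, motifs: Sequence[str] = SIGNAL_MOTIFS
) -> list[SignalHit]:
    """All (possibly overlapping) sense-strand motif matches on both strands.

    Minus-strand hits are reverse-complement matches on the stored
    sequence; coordinates are genomic.  The recorded motif is always
    the sense-strand hexamer.
    """
    hits = []
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        _check_sequence(seq, chrom)
        for motif in motifs:
            for i in _find_all(seq, motif):
                hits.append(SignalHit(chrom, "+", i, i + len(motif), motif))
            rc = reverse_complement(motif)
            for i in _find_all(seq, rc):
                hits.append(SignalHit(chrom, "-", i, i + len(motif), motif))
    return hits


def scan_oligoA(genome: GenomeSequence, min_run: int = OLIGOA_MIN_RUN) -> list[OligoARun]:
    """Maximal runs of >= min_run consecutive sense-strand As per strand.

    A run of Ts on the stored sequence is an A-run on the minus strand.
    Regex greediness guarantees maximality.
    """
    runs = []
    pat_a = re.compile(r"A{%d,}" % min_run)
    pat_t = re.compile(r"T{%d,}" % min_run)
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        for m in pat_a.finditer(seq):
            runs.append(OligoARun(chrom, "+", m.start(), m.end()))
        for m in pat_t.finditer(seq):
            runs.append(OligoARun(chrom, "-", m.start(), m.end()))
    return runs


def _merge(intervals: list[tuple[int, int, object]]) -> list[tuple[int, int, list]]:
    """Merge overlapping (>= 1 shared bp) intervals; keeps member payloads."""
    if not intervals:
        return []
    intervals = sorted(intervals, key=lambda iv: (iv[0], iv[1]))
    merged = [[intervals[0][0], intervals[0][1], [intervals[0][2]]]]
    for s, e, m in intervals[1:]:
        last = merged[-1]
        if s < last[1]:  # strict overlap; touching windows stay separate
            last[1] = max(last[1], e)
            last[2].append(m)
        else:
            merged.append([s, e, [m]])
    return [(s, e, ms) for s, e, ms in merged]


def build_windows(
    hits: Sequence[SignalHit],
    runs: Sequence[OligoARun],
    chrom_lengths: Mapping[str, int],
    up: int = SIGNAL_UP,
    down: int = SIGNAL_DOWN,
    oligoa_up: int = OLIGOA_UP,
) -> list[PasWindow]:
    """Counting windows from signal hits and oligo-A runs.

    Signal windows span [signal - up, signal_end + down) in
    transcription orientation; oligo-A windows [run - oligoa_up,
    run_end).  Windows are clipped to chromosome bounds, merged within
    each (kind, strand), and merged signal windows overlapping a merged
    oligo-A window on the same strand are removed.
    """
    raw: dict[tuple[str, str, str], list[tuple[int, int, object]]] = {}
    for h in hits:
        if h.strand == "+":
            s, e = h.start - up, h.end + down
        else:
            s, e = h.start - down, h.end + up
        s, e = max(0, s), min(chrom_lengths[h.chrom], e)
        if e > s:
            raw.setdefault((h.chrom, h.strand, "signal"), []).append((s, e, h))
    for r in runs:
        if r.strand == "+":
            s, e = r.start - oligoa_up, r.end
        else:
            s, e = r.start, r.end + oligoa_up
        s, e = max(0, s), min(chrom_lengths[r.chrom], e)
        if e > s:
            raw.setdefault((r.chrom, r.strand, "oligoA"), []).append((s, e, r))

    merged: dict[tuple[str, str, str], list[tuple[int, int, list]]] = {
        key: _merge(ivs) for key, ivs in raw.items()
    }

    windows = []
    for (chrom, strand, kind), ivs in sorted(merged.items()):
        if kind == "signal":
            killers = merged.get((chrom, strand, "oligoA"), [])
            for s, e, ms in ivs:
                if any(s < ke and ks < e for ks, ke, _ in killers):
                    continue
                windows.append(PasWindow(chrom, strand, s, e, "signal", ms))
        else:
            for s, e, ms in ivs:
                windows.append(PasWindow(chrom, strand, s, e, "oligoA", ms))
    return windows


_LOCATION_PREFERENCE = ("utr3", "exon", "intron")


def annotate_windows(
    windows: Sequence[PasWindow], genes: Sequence[GeneModel]
) -> list[PasWindow]:
    """Label each window by same-strand gene-feature overlap.

    Preference: 3'UTR > exon > intron > intergenic.  Overlap of one bp
    suffices.  The window's gene assignment is the overlapping
    representative transcript (3'UTR first, then exon, then intron).
    """
    trees: dict[tuple[str, str, str], IntervalTree] = {}

    def _add(chrom, strand, feat, s, e, gid):
        if e > s:
            trees.setdefault((chrom, strand, feat), IntervalTree()).addi(s, e, gid)

    for g in genes:
        t = g.representative_transcript if g.representative else g.transcripts[0]
        for s, e in t.utr3 or []:
            _add(t.chrom, t.strand, "utr3", s, e, g.gene_id)
        for s, e in t.exons:
            _add(t.chrom, t.strand, "exon", s, e, g.gene_id)
        for s, e in t.introns():
            _add(t.chrom, t.strand, "intron", s, e, g.gene_id)

    for w in windows:
        w.location = "intergenic"
        w.gene_id = None
        for feat in _LOCATION_PREFERENCE:
            tree = trees.get((w.chrom, w.strand, feat))
            if tree is not None:
                ov = tree.overlap(w.start, w.end)
                if ov:
                    w.location = feat
                    w.gene_id = sorted(iv.data for iv in ov)[0]
                    break
    return list(windows)


def count_window_reads(
    windows: Sequence[PasWindow],
    reads_by_sample: Mapping[str, Iterable[tuple[str, int, int, str]]],
) -> pd.DataFrame:
    """Strand-matched overlap counts of 3'end reads per window and sample.

    Reads are (chrom, start, end, strand) tuples; a read contributes to
    a window when it overlaps it by >= 1 bp and strands match, and is
    counted at most once per window.  Unstranded reads raise an error.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, w in enumerate(windows):
        trees.setdefault((w.chrom, w.strand), IntervalTree()).addi(w.start, w.end, idx)

    counts = np.zeros((len(windows), len(reads_by_sample)), dtype=np.int64)
    sample_ids = list(reads_by_sample)
    for j, sid in enumerate(sample_ids):
        for chrom, s, e, strand in reads_by_sample[sid]:
            if strand not in "+-":
                raise ValueError(f"sample {sid}: unstranded read at {chrom}:{s}-{e}")
            tree = trees.get((chrom, strand))
            if tree is None:
                continue
            for iv in tree.overlap(s, e):
                counts[iv.data, j] += 1
    return pd.DataFrame(counts, index=[w.window_id for w in windows], columns=sample_ids)


def reads_from_bam(bam_path: str, min_score: int = 20):
    """Yield (chrom, start, end, strand) for retained primary alignments."""
    import pysam

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_score:
                continue
            yield (
                read.reference_name,
                read.reference_start,
                read.reference_end,
                "-" if read.is_reverse else "+",
            )


def call_regulated_pas(
    windows: Sequence[PasWindow],
    de_table: pd.DataFrame,
    alpha: float = 0.01,
) -> list[PasWindow]:
    """Assign down / up / non / untested per window from a DE table.

    ``de_table`` must be indexed by window_id with columns ``log2fc``
    and ``padj``.  Down requires log2FC < 0 and adjusted p < alpha; up
    the mirror; windows absent from the table or with missing adjusted
    p are untested.  Table ids not matching any window are an error.
    """
    ids = {w.window_id for w in windows}
    stray = set(de_table.index) - ids
    if stray:
        raise ValueError(f"DE table contains {len(stray)} unknown window ids, e.g. {sorted(stray)[:3]}")
    for w in windows:
        if w.window_id not in de_table.index:
            w.regulation = "untested"
            continue
        row = de_table.loc[w.window_id]
        lfc, padj = float(row["log2fc"]), row["padj"]
        if pd.isna(padj):
            w.regulation = "untested"
        elif padj < alpha and lfc < 0:
            w.regulation = "down"
        elif padj < alpha and lfc > 0:
            w.regulation = "up"
        else:
            w.regulation = "non"
    return list(windows)


@dataclass
class GenePasSummary:
    gene_id: str
    transcript_class: str
    category: str  # down | up | non | untested (preference order)
    has_down_utr3_pas: bool
    has_upstream_up_pas: bool
    n_upstream_up: int


def _is_upstream(w: PasWindow, ref: PasWindow) -> bool:
    """True if w lies strictly 5' (transcription direction) of ref."""
    if w.strand == "+":
        return w.end <= ref.start
    return w.start >= ref.end


def summarize_gene(
    gene_id: str,
    gene_windows: Sequence[PasWindow],
    transcript_class: str,
) -> GenePasSummary:
    """Per-gene poly(A)-site category and upstream-shift flags.

    Category preference: down-regulated PAS in a 3'UTR, then any
    up-regulated PAS, then any non-regulated PAS, then no tested PAS.
    Upstream up-regulated windows are counted strictly 5' of the
    3'-most down-regulated 3'UTR window.
    """
    down_utr3 = [w for w in gene_windows if w.regulation == "down" and w.location == "utr3"]
    ups = [w for w in gene_windows if w.regulation == "up"]
    nons = [w for w in gene_windows if w.regulation == "non"]

    if down_utr3:
        category = "down"
    elif ups:
        category = "up"
    elif nons:
        category = "non"
    else:
        category = "untested"

    n_upstream_up = 0
    if down_utr3:
        # 3'-most in transcription direction
        ref = max(down_utr3, key=lambda w: w.end if w.strand == "+" else -w.start)
        n_upstream_up = sum(1 for w in ups if _is_upstream(w, ref))
    return GenePasSummary(
        gene_id=gene_id,
        transcript_class=transcript_class,
        category=category,
        has_down_utr3_pas=bool(down_utr3),
        has_upstream_up_pas=n_upstream_up >= 1,
        n_upstream_up=n_upstream_up,
    )


def summarize_genes(
    genes: Sequence[GeneModel],
    windows: Sequence[PasWindow],
    transcript_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Gene-level summary table over annotated, called windows.

    Windows are attributed to a gene when they overlap its
    representative transcript span on the same strand.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, w in enumerate(windows):
        trees.setdefault((w.chrom, w.strand), IntervalTree()).addi(w.start, w.end, idx)
    rows = []
    for g in genes:
        t = g.representative_transcript if g.representative else g.transcripts[0]
        tree = trees.get((t.chrom, t.strand))
        gw = (
            [windows[iv.data] for iv in tree.overlap(t.span_start, t.span_end)]
            if tree is not None
            else []
        )
        summ = summarize_gene(g.gene_id, gw, transcript_classes.get(g.gene_id, "unclassified"))
        rows.append(
            {
                "gene_id": summ.gene_id,
                "transcript_class": summ.transcript_class,
                "category": summ.category,
                "has_down_utr3_pas": summ.has_down_utr3_pas,
                "has_upstream_up_pas": summ.has_upstream_up_pas,
                "n_upstream_up": summ.n_upstream_up,
            }
        )
    return pd.DataFrame(rows)


def windows_to_bed(windows: Sequence[PasWindow], de_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """BED6 frame (name = kind:location, score = -10*log10 adj p, capped at 1000)."""
    rows = []
    for w in windows:
        score = 0
        if de_table is not None and w.window_id in de_table.index:
            padj = de_table.loc[w.window_id, "padj"]
            if not pd.isna(padj):
                score = min(1000, int(round(-10 * np.log10(max(padj, 1e-300)))))
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "name": f"{w.kind}:{w.location or 'NA'}",
                "score": score,
                "strand": w.strand,
            }
        )
    return pd.DataFrame(rows)
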