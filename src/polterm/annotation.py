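"""Gene annotation handling.

Parses GTF (GENCODE attribute dialect) into strand-aware gene/transcript
models with 0-based half-open coordinates, selects each gene's
representative transcript by RNAPII promoter/terminator occupancy, and
computes gene-level sequence features (genomic length, poly(A) signal
content).

Coordinate convention: all internal coordinates are 0-based half-open;
GTF's 1-based inclusive coordinates are converted on read and write.
"TSS" is the transcript's 5' end in transcription direction (span_start
on '+', span_end - 1 on '-'); "TTS" is the opposite end.  "Gene length"
means the genomic span length of the selected transcript, introns
included.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: canonical poly(A) signal hexamers, sense strand
CANONICAL_PAS_MOTIFS = ("AATAAA", "ATTAAA")

#: transcripts shorter than this (genomic span, bp) are excluded from
#: scaled metagene profiling; guarantees a gene body of >= 180 bp after
#: removing the two 1.5-kb inner flanks.
MIN_METAGENE_LENGTH = 3180


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSequence:
    """Uppercase nucleotide sequences over {A,C,G,T,N}, one per chromosome.

    Backed either by an in-memory dict (synthetic genomes) or a
    pyfaidx.Fasta handle (on-disk FASTA with .fai index).
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        """Sequence of [start, end) on the forward strand."""
        seq = self._seqs[chrom]
        if start is None and end is None:
            return seq
        if start < 0 or end > len(seq):
            raise ValueError(
                f"span [{start}, {end}) exceeds chromosome {chrom!r} bounds [0, {len(seq)})"
            )
        return seq[start:end]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}


@dataclass
class TranscriptModel:
    """One transcript: genomic span, ordered exons, optional 3'UTR."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] | None = None
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.span_end <= self.span_start:
            raise ValueError(
                f"{self.transcript_id}: empty span [{self.span_start}, {self.span_end})"
            )
        self.exons = sorted(self.exons)

    @property
    def genomic_length(self) -> int:
        return self.span_end - self.span_start

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1

    @property
    def tts(self) -> int:
        return self.span_end - 1 if self.strand == "+" else self.span_start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    representative: str | None = None
    biotype: str | None = None

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    @property
    def representative_transcript(self) -> TranscriptModel:
        if self.representative is None:
            raise ValueError(f"{self.gene_id}: representative transcript not set")
        return self.transcript(self.representative)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if "gene_id" not in attrs:
        raise GtfParseError(f"line {lineno}: cannot parse attribute field: {attr_field!r}")
    return attrs


def read_gtf(path: str) -> list[GeneModel]:
    """Parse a GENCODE-style GTF into GeneModels.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open.  Records with an unknown strand symbol are dropped with a
    warning; genes that end up with zero exons are dropped with a
    warning; structurally malformed lines raise :class:`GtfParseError`
    naming the line number.
    """
    transcripts: dict[str, TranscriptModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    utr3s: dict[str, list[tuple[int, int]]] = {}
    utrs: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    gene_biotype: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise GtfParseError(f"line {lineno}: end {end1} < start {start1}")
            start, end = start1 - 1, end1  # to 0-based half-open
            if strand not in "+-":
                log.warning("line %d: unknown strand %r, record dropped", lineno, strand)
                continue
            attrs = _parse_attributes(attr, lineno)
            gid = attrs["gene_id"]
            if feature == "gene":
                if gid not in gene_biotype:
                    gene_order.append(gid)
                gene_biotype[gid] = attrs.get("gene_type", attrs.get("gene_biotype", ""))
                continue
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if gid not in gene_biotype:
                gene_order.append(gid)
                gene_biotype[gid] = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            if feature == "transcript":
                tag = tuple(m.group(2) for m in re.finditer(r'tag\s+"([^"]*)"', attr))
                transcripts[tid] = TranscriptModel(
                    gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                    span_start=start, span_end=end, tags=tag,
                )
            elif feature == "exon":
                exons.setdefault(tid, []).append((start, end))
                if tid not in transcripts:
                    # transcript feature may be absent; grow a hull later
                    transcripts[tid] = TranscriptModel(
                        gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                        span_start=start, span_end=end,
                    )
            elif feature in ("three_prime_UTR", "three_prime_utr"):
                utr3s.setdefault(tid, []).append((start, end))
            elif feature == "UTR":
                utrs.setdefault(tid, []).append((start, end))
            elif feature == "CDS":
                cds.setdefault(tid, []).append((start, end))

    genes: dict[str, GeneModel] = {}
    for tid, t in transcripts.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            continue
        t.exons = ex
        t.span_start = min(t.span_start, ex[0][0])
        t.span_end = max(t.span_end, ex[-1][1])
        u3 = sorted(utr3s.get(tid, []))
        if not u3 and tid in utrs and tid in cds:
            # generic UTR features: 3' side of the CDS hull, strand-aware
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
            for s, e in sorted(utrs[tid]):
                if (t.strand == "+" and s >= ce) or (t.strand == "-" and e <= cs):
                    u3.append((s, e))
        t.utr3 = sorted(u3) if u3 else None
        g = genes.get(t.gene_id)
        if g is None:
            g = genes[t.gene_id] = GeneModel(
                gene_id=t.gene_id, biotype=gene_biotype.get(t.gene_id) or None
            )
        g.transcripts.append(t)

    out = []
    for gid in gene_order or list(genes):
        if gid not in genes:
            log.warning("gene %s has no transcript with exons, dropped", gid)
            continue
        out.append(genes[gid])
    for gid in genes:
        if gid not in (gene_order or genes):
            out.append(genes[gid])
    return out


def write_gtf(genes: Iterable[GeneModel], path: str) -> None:
    """Write GeneModels back to GTF (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for g in genes:
            start = min(t.span_start for t in g.transcripts)
            end = max(t.span_end for t in g.transcripts)
            battr = f' gene_type "{g.biotype}";' if g.biotype else ""
            fh.write(
                f"{g.chrom}\tpolterm\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";{battr}\n'
            )
            for t in g.transcripts:
                base = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tpolterm\ttranscript\t{t.span_start + 1}\t{t.span_end}\t.\t"
                    f"{t.strand}\t.\t{base}{battr}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tpolterm\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{base}\n"
                    )
                for s, e in t.utr3 or []:
                    fh.write(
                        f"{t.chrom}\tpolterm\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{base}\n"
                    )


DEFAULT_LOW_CONFIDENCE_TAGS = (
    "mRNA_start_NF",
    "mRNA_end_NF",
    "cds_start_NF",
    "cds_end_NF",
)


def filter_confident(
    genes: Iterable[GeneModel],
    protein_coding_only: bool = True,
    drop_tags: Sequence[str] = DEFAULT_LOW_CONFIDENCE_TAGS,
) -> list[GeneModel]:
    """Keep high-confidence protein-coding annotation.

    Drops non-protein-coding genes (when a biotype is recorded) and
    transcripts carrying annotation tags that flag incomplete models.
    """
    out = []
    for g in genes:
        if protein_coding_only and g.biotype and g.biotype != "protein_coding":
            continue
        kept = [t for t in g.transcripts if not set(t.tags) & set(drop_tags)]
        if kept:
            out.append(GeneModel(g.gene_id, kept, g.representative, g.biotype))
    return out


def _merged_windows(t: TranscriptModel, flank: int) -> list[tuple[int, int]]:
    """±flank windows around TSS and TTS, merged if they overlap, clipped at 0."""
    w = sorted(
        [
            (max(0, t.tss - flank), t.tss + flank),
            (max(0, t.tts - flank), t.tts + flank),
        ]
    )
    if w[0][1] >= w[1][0]:
        return [(w[0][0], max(w[0][1], w[1][1]))]
    return w


def select_representative_transcript(gene: GeneModel, rnapii_tracks, flank: int = 3000) -> str:
    """Pick the transcript with most library-size-normalized RNAPII signal
    in the ±3 kb windows around its TSS and TTS (union, so overlapping
    windows are not double-counted).

    Ties go to the longer transcript, then the lexicographically
    smallest transcript id.  With no tracks, falls back to the longest
    transcript (same tie-break) and logs the fallback.
    """
    if not gene.transcripts:
        raise ValueError(f"{gene.gene_id}: no transcripts")
    if not rnapii_tracks:
        log.info("%s: no RNAPII tracks, falling back to longest transcript", gene.gene_id)
        best = sorted(
            gene.transcripts, key=lambda t: (-t.genomic_length, t.transcript_id)
        )[0]
        return best.transcript_id

    scored = []
    for t in gene.transcripts:
        score = 0.0
        for track in rnapii_tracks:
            for s, e in _merged_windows(t, flank):
                score += float(track.values(t.chrom, s, e).sum()) / track.library_size
        scored.append((-score, -t.genomic_length, t.transcript_id))
    scored.sort()
    return scored[0][2]


def metagene_length_filter(t: TranscriptModel, min_length: int = MIN_METAGENE_LENGTH) -> bool:
    """True iff the transcript is long enough for scaled metagene profiling."""
    return t.genomic_length >= min_length


def count_motif_occurrences(seq: str, motif: str) -> int:
    """Occurrences of motif in seq, overlapping matches counted."""
    n = 0
    i = seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def polya_signal_content(
    gene: GeneModel,
    genome: GenomeSequence,
    motifs: Sequence[str] = CANONICAL_PAS_MOTIFS,
) -> float:
    """Canonical poly(A) signals per bp of gene length.

    Counts sense-strand AATAAA/ATTAAA occurrences within the
    representative transcript's genomic span and divides by the span
    length.
    """
    t = gene.representative_transcript
    seq = genome.sequence(t.chrom, t.span_start, t.span_end)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return sum(count_motif_occurrences(seq, m) for m in motifs) / t.genomic_length


def representative_table(genes: Sequence[GeneModel], genome: GenomeSequence | None = None):
    """TSV-ready table of representative transcripts per gene."""
    import pandas as pd

    rows = []
    for g in genes:
        t = g.representative_transcript
        row = {
            "gene_id": g.gene_id,
            "transcript_id": t.transcript_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "start": t.span_start,
            "end": t.span_end,
            "length": t.genomic_length,
        }
        if genome is not None:
            row["polyA_content"] = polya_signal_content(g, genome)
        rows.append(row)
    return pd.DataFrame(rows)
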