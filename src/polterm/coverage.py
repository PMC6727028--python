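"""Per-base coverage tracks from alignments or bedGraph, and region extraction.

A :class:`CoverageTrack` stores dense per-base counts per chromosome
(two layers for stranded RNA libraries), the retained-read library size,
and sample metadata.  Regions are extracted 5'->3' in transcription
direction, zero-filled beyond chromosome bounds.

Alignment filtering follows the mapping-quality rule: primary, mapped
alignments with MAPQ >= 20 are retained (the SAM MAPQ field is the
"alignment score" this filter acts on); secondary and supplementary
alignments are excluded, duplicates are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20


@dataclass
class CoverageTrack:
    """Per-base coverage for one sequencing sample.

    ``strandedness``: 'unstranded' (ChIP), 'forward' (read strand equals
    transcript strand) or 'reverse' (opposite).  Stranded tracks keep
    separate forward/reverse-read layers so a gene's sense coverage can
    be selected.
    """

    sample_id: str
    assay: str = ""
    condition: str = ""
    replicate: int = 0
    library_size: float = 0.0
    strandedness: str = "unstranded"
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    fwd: dict[str, np.ndarray] = field(default_factory=dict)
    rev: dict[str, np.ndarray] = field(default_factory=dict)
    read_intervals: dict[str, np.ndarray] | None = None  # (start, end, is_reverse) rows
    mean_read_length: float | None = None

    def __post_init__(self) -> None:
        if self.strandedness not in ("unstranded", "forward", "reverse"):
            raise ValueError(f"bad strandedness {self.strandedness!r}")

    def _layer(self, store: dict[str, np.ndarray], chrom: str) -> np.ndarray | None:
        return store.get(chrom)

    def values(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> np.ndarray:
        """Per-base counts over [start, end); out-of-bounds zero-filled.

        ``strand`` is the *transcript* sense strand.  For stranded
        tracks only sense reads contribute; for unstranded tracks (or
        strand=None) all reads do.  The returned vector is in genomic
        (left-to-right) order; callers reverse for '-' orientation.
        """
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            raise ValueError("end must exceed start")
        clen = self.chrom_lengths[chrom]
        out = np.zeros(end - start, dtype=np.float64)
        lo, hi = max(start, 0), min(end, clen)
        if lo >= hi:
            return out
        if self.strandedness == "unstranded" or strand is None:
            layers = [self.fwd, self.rev]
        else:
            want_reverse = (strand == "-") == (self.strandedness == "forward")
            layers = [self.rev if want_reverse else self.fwd]
        for store in layers:
            arr = self._layer(store, chrom)
            if arr is not None:
                out[lo - start : hi - start] += arr[lo:hi]
        return out

    def count_reads(self, chrom: str, start: int, end: int) -> int:
        """Reads overlapping [start, end) by >= 1 bp (alignment-backed tracks)."""
        if self.read_intervals is None:
            raise ValueError(
                f"track {self.sample_id!r} is not alignment-backed; cannot count reads"
            )
        iv = self.read_intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return 0
        return int(np.count_nonzero((iv[:, 0] < end) & (iv[:, 1] > start)))

    def total_coverage(self) -> float:
        return float(
            sum(a.sum(dtype=np.float64) for a in self.fwd.values())
            + sum(a.sum(dtype=np.float64) for a in self.rev.values())
        )


def coverage_from_alignments(
    bam_path: str,
    min_score: int = DEFAULT_MIN_MAPQ,
    sample_id: str = "",
    assay: str = "",
    condition: str = "",
    replicate: int = 0,
    strandedness: str = "unstranded",
    keep_read_intervals: bool = True,
) -> CoverageTrack:
    """Build a coverage track from an indexed BAM.

    Retains primary, mapped alignments with MAPQ >= ``min_score``;
    coverage at a base is the number of retained alignments whose
    aligned segment (reference start to reference end) covers it.
    ``library_size`` is the retained-alignment count.
    """
    import pysam

    bam = pysam.AlignmentFile(bam_path, "rb")
    try:
        if not bam.has_index():
            raise FileNotFoundError(f"{bam_path}: missing BAM index (.bai)")
    except (ValueError, AttributeError) as exc:
        raise FileNotFoundError(f"{bam_path}: missing BAM index (.bai)") from exc

    chrom_lengths = dict(zip(bam.references, bam.lengths))
    fwd = {c: np.zeros(l, dtype=np.float64) for c, l in chrom_lengths.items()}
    rev: dict[str, np.ndarray] = {}
    if strandedness != "unstranded":
        rev = {c: np.zeros(l, dtype=np.float64) for c, l in chrom_lengths.items()}
    intervals: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_lengths}

    n_retained = 0
    total_len = 0
    for read in bam.fetch():
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_score:
            continue
        s, e = read.reference_start, read.reference_end
        chrom = read.reference_name
        target = rev if (strandedness != "unstranded" and read.is_reverse) else fwd
        target[chrom][s:e] += 1
        n_retained += 1
        total_len += e - s
        if keep_read_intervals:
            intervals[chrom].append((s, e, int(read.is_reverse)))
    bam.close()

    if n_retained == 0:
        raise ValueError(f"{bam_path}: no alignments retained (library size 0)")

    return CoverageTrack(
        sample_id=sample_id or bam_path,
        assay=assay,
        condition=condition,
        replicate=replicate,
        library_size=float(n_retained),
        strandedness=strandedness,
        chrom_lengths=chrom_lengths,
        fwd=fwd,
        rev=rev,
        read_intervals={
            c: np.array(v, dtype=np.int64).reshape(-1, 3) for c, v in intervals.items()
        }
        if keep_read_intervals
        else None,
        mean_read_length=total_len / n_retained,
    )


def read_bedgraph(
    path: str,
    chrom_lengths: Mapping[str, int],
    library_size: float | None = None,
    sidecar: str | None = None,
    sample_id: str = "",
    assay: str = "",
    condition: str = "",
    replicate: int = 0,
    strandedness: str = "unstranded",
    rev_path: str | None = None,
    mean_read_length: float | None = None,
) -> CoverageTrack:
    """Read a 0-based half-open 4-column bedGraph into a track.

    Overlapping records are summed.  The library size must come from
    ``library_size`` or a two-column ``sidecar`` TSV (sample_id,
    library_size).  For stranded tracks, ``rev_path`` holds the
    reverse-read layer.
    """
    if library_size is None and sidecar is not None:
        sid = sample_id or path
        with open(sidecar) as fh:
            for line in fh:
                parts = line.split()
                if parts and parts[0] == sid:
                    library_size = float(parts[1])
                    break
    if library_size is None:
        raise ValueError(f"{path}: library size not supplied (flag or sidecar)")
    if library_size < 1:
        raise ValueError(f"{path}: library_size must be >= 1")

    def _load(p: str) -> dict[str, np.ndarray]:
        arrs = {c: np.zeros(l, dtype=np.float64) for c, l in chrom_lengths.items()}
        with open(p) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                s, e, v = int(s), int(e), float(v)
                if v < 0:
                    raise ValueError(f"{p} line {lineno}: negative coverage value {v}")
                if chrom not in arrs:
                    raise KeyError(f"{p} line {lineno}: unknown chromosome {chrom!r}")
                arrs[chrom][s:e] += v
        return arrs

    fwd = _load(path)
    rev = _load(rev_path) if rev_path is not None else {}
    return CoverageTrack(
        sample_id=sample_id or path,
        assay=assay,
        condition=condition,
        replicate=replicate,
        library_size=float(library_size),
        strandedness=strandedness,
        chrom_lengths=dict(chrom_lengths),
        fwd=fwd,
        rev=rev,
        mean_read_length=mean_read_length,
    )


def write_bedgraph(track: CoverageTrack, path: str, layer: str = "fwd") -> None:
    """Write one layer of a track as run-length-merged bedGraph."""
    store = track.fwd if layer == "fwd" else track.rev
    with open(path, "w") as fh:
        for chrom in sorted(store):
            arr = store[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


@dataclass
class RegionCoverage:
    """Per-base coverage for one region, ordered 5'->3' in transcription direction."""

    values: np.ndarray
    chrom: str
    start: int  # genomic (left) start of the extracted span
    strand: str
    gene_id: str = ""
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


def extract_region(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    gene_id: str = "",
) -> RegionCoverage:
    """Extract [start, end) oriented 5'->3'; '-' strand vectors are reversed.

    For stranded RNA tracks only reads on the gene's sense strand
    contribute; overhang beyond chromosome bounds is zero-filled.
    """
    vals = track.values(chrom, start, end, strand=strand)
    if strand == "-":
        vals = vals[::-1].copy()
    return RegionCoverage(
        values=vals, chrom=chrom, start=start, strand=strand,
        gene_id=gene_id, sample_id=track.sample_id,
    )


def rpm(count: float, library_size: float) -> float:
    return count / library_size * 1e6


def promoter_occupancy(track: CoverageTrack, t, flank: int = 3000) -> float:
    """Reads overlapping the TSS +/- flank window, in reads per million.

    A read counts once if it overlaps the window by >= 1 bp.  For
    tracks without stored read intervals (bedGraph input) the coverage
    area over the window divided by the mean read length is used
    instead; this requires ``mean_read_length`` to be recorded.
    """
    start, end = t.tss - flank, t.tss + flank
    if track.read_intervals is not None:
        n = track.count_reads(t.chrom, start, end)
    elif track.mean_read_length:
        n = track.values(t.chrom, start, end).sum() / track.mean_read_length
    else:
        raise ValueError(
            f"track {track.sample_id!r}: promoter occupancy needs read intervals "
            "or a recorded mean read length"
        )
    return rpm(float(n), track.library_size)


def promoter_log2fc(ctrl_tracks, treated_tracks, t, flank: int = 3000, pseudocount: float = 1.0) -> float:
    """log2 fold-change of promoter occupancy, treated over control.

    Computed on replicate-mean RPM per condition with a pseudocount.
    """
    c = float(np.mean([promoter_occupancy(tr, t, flank) for tr in ctrl_tracks]))
    x = float(np.mean([promoter_occupancy(tr, t, flank) for tr in treated_tracks]))
    return float(np.log2((x + pseudocount) / (c + pseudocount)))


def condition_mean_rpm(
    tracks: Iterable[CoverageTrack],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    gene_id: str = "",
) -> RegionCoverage:
    """Replicate-mean RPM-normalized coverage vector for one condition.

    Each replicate's vector is scaled to reads-per-million by its own
    library size before averaging.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks supplied")
    acc = None
    for tr in tracks:
        v = extract_region(tr, chrom, start, end, strand, gene_id).values
        v = v / tr.library_size * 1e6
        acc = v if acc is None else acc + v
    return RegionCoverage(
        values=acc / len(tracks), chrom=chrom, start=start, strand=strand, gene_id=gene_id,
        sample_id=",".join(tr.sample_id for tr in tracks),
    )
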