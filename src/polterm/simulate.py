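"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the study design the analysis assumes: paired
control/inhibitor conditions with three replicates each; a subset of
"affected" genes whose polymerase coverage and transcription truncate
at a per-gene position t*L inside the gene body; a P-Ser2 occupancy
peak relocated to the truncation point under treatment; and 3'end
read counts shifting from the distal 3'UTR poly(A) window to a planted
upstream window in affected genes.

One synthetic chromosome carries non-overlapping genes on alternating
strands.  The genome is random ACGT with a sense-strand AATAAA planted
in each 3'UTR (the distal poly(A) signal), a second signal planted at
t*L for affected genes (the proximal site), and decoy oligo-A runs
planted next to extra intergenic signals so the internal-priming
exclusion has planted positives.  Everything is deterministic given
the configuration seed.

Coverage model (expected reads/bp, before Poisson sampling): a uniform
gene body at ``body_depth``, a Gaussian promoter peak at the TSS, and a
mild TTS bump; treated affected genes multiply the body (and TTS bump)
by a logistic decay centred at t*L.  P-Ser2 ramps toward the 3' end in
control and re-centres its peak at t*L under treatment.  Nuclear RNA
mirrors the polymerase truncation with a sharper decay and is
strand-specific.  3'end counts are negative-binomial
(variance mu + alpha*mu^2) around the planted window masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeSequence, TranscriptModel, reverse_complement
from .coverage import CoverageTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Lengths are drawn log-uniformly between ``length_min`` and
    ``length_max`` (bp); ``fraction_affected`` of genes truncate at a
    fraction t ~ U(t_min, t_max) of their length under treatment.
    ``body_depth`` is expected reads per bp in the gene body;
    ``promoter_height`` multiplies it at the TSS peak.  3'end counts
    average ``mean_3p_reads`` per gene and sample with negative-binomial
    dispersion ``nb_dispersion``; treated affected genes move
    ``pas_shift_fraction`` of the distal window's mass upstream.
    """

    n_genes: int = 300
    length_min: int = 4_000
    length_max: int = 300_000
    fraction_affected: float = 0.4
    t_min: float = 0.3
    t_max: float = 0.8
    body_depth: float = 2.0
    promoter_height: float = 8.0
    tts_bump: float = 2.0
    background_depth: float = 0.05
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    mean_3p_reads: float = 300.0
    distal_mass: float = 0.95
    pas_shift_fraction: float = 0.7
    intergenic_gap: int = 8_000
    decoy_fraction: float = 0.1
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_affected <= 1:
            raise ValueError("fraction_affected must lie in [0, 1]")
        if not 0 < self.t_min <= self.t_max < 1:
            raise ValueError("truncation fractions must lie in (0, 1)")
        for name in ("n_genes", "length_min", "length_max", "body_depth", "mean_3p_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _plant_sense(seq: np.ndarray, t: TranscriptModel, offset: int, motif: str) -> int:
    """Plant a sense-strand motif at oriented offset from the TSS.

    Returns the genomic start of the planted hexamer.
    """
    if t.strand == "+":
        g = t.span_start + offset
        _plant(seq, g, motif)
    else:
        g = t.span_end - offset - len(motif)
        _plant(seq, g, reverse_complement(motif))
    return g


def _make_exons(rng: np.random.Generator, start: int, length: int) -> list[tuple[int, int]]:
    k_max = int(min(20, max(3, length // 1500)))
    k = int(rng.integers(3, k_max + 1))
    lens = [int(rng.integers(200, 601))]
    lens += [int(rng.integers(150, 501)) for _ in range(k - 2)]
    lens.append(int(rng.integers(400, 1201)))
    intron_total = length - sum(lens)
    n_introns = k - 1
    w = rng.random(n_introns) + 0.2
    ilens = np.floor(w / w.sum() * intron_total).astype(int)
    ilens[-1] += intron_total - ilens.sum()
    ilens = np.maximum(ilens, 50)
    # re-absorb any clamping surplus into the largest intron
    ilens[np.argmax(ilens)] -= ilens.sum() - intron_total
    exons = []
    pos = start
    for i, el in enumerate(lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_introns:
            pos += int(ilens[i])
    # absorb rounding drift into the last exon
    s_last, _ = exons[-1]
    exons[-1] = (s_last, start + length)
    return exons


def simulate_annotation(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], GenomeSequence, pd.DataFrame]:
    """Genes, genome and truth table for one synthetic chromosome."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    lengths = np.exp(
        rng.uniform(np.log(cfg.length_min), np.log(cfg.length_max), cfg.n_genes)
    ).astype(int)
    n_aff = int(round(cfg.n_genes * cfg.fraction_affected))
    affected = np.zeros(cfg.n_genes, dtype=bool)
    # longer genes are more vulnerable to truncation (they carry more
    # internal poly(A) signals): affection probability grows with length
    # rank while the overall affected fraction stays fraction_affected
    rank = np.empty(cfg.n_genes)
    rank[np.argsort(lengths, kind="stable")] = np.arange(1, cfg.n_genes + 1)
    w = rank / rank.sum()
    affected[rng.choice(cfg.n_genes, size=n_aff, replace=False, p=w)] = True
    tvals = np.where(affected, rng.uniform(cfg.t_min, cfg.t_max, cfg.n_genes), np.nan)
    decoy = rng.random(cfg.n_genes) < cfg.decoy_fraction

    margin = 5000
    starts = np.empty(cfg.n_genes, dtype=int)
    cur = margin
    for i, L in enumerate(lengths):
        starts[i] = cur
        cur += int(L) + cfg.intergenic_gap
    genome_len = cur + margin

    seq = _BASES[rng.integers(0, 4, genome_len)]

    genes: list[GeneModel] = []
    rows = []
    for i in range(cfg.n_genes):
        gid = f"SIMG{i:05d}"
        tid = f"SIMT{i:05d}"
        L = int(lengths[i])
        strand = "+" if i % 2 == 0 else "-"
        s0 = int(starts[i])
        exons = _make_exons(rng, s0, L)
        t = TranscriptModel(
            gene_id=gid, transcript_id=tid, chrom=cfg.chrom, strand=strand,
            span_start=s0, span_end=s0 + L, exons=exons,
        )
        # 3'UTR: 3'-terminal stretch of the 3'-most exon
        if strand == "+":
            es, ee = exons[-1]
            u = min(300, ee - es - 50)
            t.utr3 = [(ee - u, ee)]
        else:
            es, ee = exons[0]
            u = min(300, ee - es - 50)
            t.utr3 = [(es, es + u)]

        distal_pos = _plant_sense(seq, t, L - 106, "AATAAA")
        proximal_pos = -1
        if affected[i]:
            q = int(round(tvals[i] * L))
            q = min(q, L - 600)
            proximal_pos = _plant_sense(seq, t, q, "AATAAA")
        decoy_pos = -1
        if decoy[i]:
            # decoy signal + overlapping oligo-A run in the downstream gap
            p = s0 + L + 2000
            _plant(seq, p, "AATAAA")
            _plant(seq, p + 20, "A" * 12)
            decoy_pos = p

        g = GeneModel(gene_id=gid, transcripts=[t], representative=tid,
                      biotype="protein_coding")
        genes.append(g)
        rows.append(
            {
                "gene_id": gid, "transcript_id": tid, "chrom": cfg.chrom,
                "strand": strand, "span_start": s0, "span_end": s0 + L,
                "length": L, "tss": t.tss, "tts": t.tts,
                "affected": bool(affected[i]),
                "t": float(tvals[i]) if affected[i] else np.nan,
                "distal_pas_pos": int(distal_pos),
                "proximal_pas_pos": int(proximal_pos),
                "decoy_pos": int(decoy_pos),
                "n_exons": len(exons),
            }
        )

    genome = GenomeSequence({cfg.chrom: seq.tobytes().decode("ascii")})
    truth = pd.DataFrame(rows)
    return genes, genome, truth


def _oriented_positions(t: TranscriptModel, pad: int) -> np.ndarray:
    """Transcription-direction offsets (0 at TSS) over [span-pad, span+pad)."""
    n = t.genomic_length + 2 * pad
    q = np.arange(n, dtype=np.float64) - pad
    if t.strand == "-":
        q = q[::-1]
    return q


def _decay(q: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip((q - center) / scale, -60, 60)))


def expected_profile(
    t: TranscriptModel,
    assay: str,
    condition: str,
    affected: bool,
    tfrac: float,
    cfg: SimulationConfig,
    pad: int = 1500,
) -> np.ndarray:
    """Expected reads/bp over [span_start - pad, span_end + pad), genomic order."""
    L = t.genomic_length
    q = _oriented_positions(t, pad)
    body_mask = (q >= 0) & (q < L)
    d = cfg.body_depth
    truncate = condition == "treated" and affected
    tc = tfrac * L if truncate else None

    if assay in ("RNAPII", "SPT6"):
        body = d * body_mask.astype(float)
        prom = cfg.promoter_height * d * np.exp(-0.5 * (q / 300.0) ** 2)
        bump = cfg.tts_bump * d * np.exp(-0.5 * ((q - L) / 200.0) ** 2)
        if truncate:
            # initiation is unaffected; elongating polymerase is lost at t*L
            dec = _decay(q, tc, max(50.0, 0.02 * L))
            prof = body * dec + prom + bump * dec
        else:
            prof = body + prom + bump
    elif assay == "P-Ser2":
        if truncate:
            # elongation mark accumulates up to, and peaks at, the truncation point
            ramp = 0.25 + 0.75 * np.clip(q, 0, tc) / max(tc, 1.0)
            peak = 0.9 * np.exp(-0.5 * ((q - tc) / (0.03 * L)) ** 2)
            prof = d * (ramp * _decay(q, tc, max(50.0, 0.02 * L)) + peak) * body_mask
        else:
            ramp = 0.25 + 0.75 * np.clip(q, 0, L) / L
            prof = d * ramp * body_mask
            prof += 0.5 * d * np.exp(-0.5 * ((q - L) / 200.0) ** 2)
    elif assay == "P-Ser5":
        prof = 0.3 * d * body_mask.astype(float)
        prof += cfg.promoter_height * d * np.exp(-0.5 * (q / 250.0) ** 2)
        if truncate:
            prof *= np.where(body_mask, _decay(q, tc, max(50.0, 0.02 * L)), 1.0)
    elif assay == "nucRNA":
        prof = d * body_mask.astype(float)
        if truncate:
            prof *= _decay(q, tc, max(50.0, 0.02 * L))
    else:
        raise ValueError(f"unknown assay {assay!r}")
    return prof


CHIP_ASSAYS = ("RNAPII", "P-Ser2", "P-Ser5", "SPT6")


def _expected_genome_array(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    assay: str,
    condition: str,
    cfg: SimulationConfig,
    genome_len: int,
    strand_split: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    fwd = np.full(genome_len, cfg.background_depth, dtype=np.float64)
    rev = np.full(genome_len, cfg.background_depth, dtype=np.float64) if strand_split else None
    tmap = truth.set_index("gene_id")
    pad = 1500
    for g in genes:
        t = g.representative_transcript
        row = tmap.loc[g.gene_id]
        prof = expected_profile(
            t, assay, condition, bool(row["affected"]),
            float(row["t"]) if row["affected"] else 0.0, cfg, pad=pad,
        )
        lo = t.span_start - pad
        hi = t.span_end + pad
        lo_c, hi_c = max(lo, 0), min(hi, genome_len)
        target = fwd if (rev is None or t.strand == "+") else rev
        target[lo_c:hi_c] += prof[lo_c - lo : hi_c - lo]
    return fwd, rev


def simulate_chip_coverage(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: GenomeSequence,
    assays: Sequence[str] = ("RNAPII",),
    conditions: Sequence[str] = ("control", "treated"),
) -> list[CoverageTrack]:
    """Poisson-sampled per-base ChIP coverage tracks, one per replicate."""
    genome_len = genome.length(cfg.chrom)
    chrom_lengths = {cfg.chrom: genome_len}
    tracks = []
    for assay in assays:
        for condition in conditions:
            lam, _ = _expected_genome_array(
                genes, truth, assay, condition, cfg, genome_len, strand_split=False
            )
            for rep in range(1, cfg.n_replicates + 1):
                factor = float(np.exp(rng.normal(0.0, 0.05)))
                counts = rng.poisson(lam * factor).astype(np.uint16)
                tracks.append(
                    CoverageTrack(
                        sample_id=f"{assay}_{condition}_{rep}",
                        assay=assay,
                        condition=condition,
                        replicate=rep,
                        library_size=float(max(counts.sum(dtype=np.float64), 1.0)),
                        strandedness="unstranded",
                        chrom_lengths=dict(chrom_lengths),
                        fwd={cfg.chrom: counts},
                    )
                )
    return tracks


def simulate_rna_coverage(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: GenomeSequence,
    conditions: Sequence[str] = ("control", "treated"),
) -> list[CoverageTrack]:
    """Strand-specific nuclear RNA coverage mirroring the truncation."""
    genome_len = genome.length(cfg.chrom)
    chrom_lengths = {cfg.chrom: genome_len}
    tracks = []
    for condition in conditions:
        fwd, rev = _expected_genome_array(
            genes, truth, "nucRNA", condition, cfg, genome_len, strand_split=True
        )
        for rep in range(1, cfg.n_replicates + 1):
            factor = float(np.exp(rng.normal(0.0, 0.05)))
            cf = rng.poisson(fwd * factor).astype(np.uint16)
            cr = rng.poisson(rev * factor).astype(np.uint16)
            tracks.append(
                CoverageTrack(
                    sample_id=f"nucRNA_{condition}_{rep}",
                    assay="nucRNA",
                    condition=condition,
                    replicate=rep,
                    library_size=float(max(cf.sum(dtype=np.float64) + cr.sum(dtype=np.float64), 1.0)),
                    strandedness="forward",
                    chrom_lengths=dict(chrom_lengths),
                    fwd={cfg.chrom: cf},
                    rev={cfg.chrom: cr},
                )
            )
    return tracks


def expected_pas_masses(
    truth: pd.DataFrame, cfg: SimulationConfig, expression: Mapping[str, float]
) -> pd.DataFrame:
    """Expected 3'end read mass per planted window, gene and condition.

    Control puts ``distal_mass`` of a gene's expression on its distal
    3'UTR window; treated affected genes move ``pas_shift_fraction`` of
    that distal mass to the proximal window.  Summed over windows, the
    expected mass per gene is identical across conditions.
    """
    rows = []
    for _, r in truth.iterrows():
        e = expression[r["gene_id"]]
        md = cfg.distal_mass * e
        mp = (1 - cfg.distal_mass) * e if r["affected"] else 0.0
        if r["affected"]:
            shift = cfg.pas_shift_fraction
            rows.append(
                {
                    "gene_id": r["gene_id"],
                    "distal_control": md, "proximal_control": mp,
                    "distal_treated": md * (1 - shift),
                    "proximal_treated": mp + md * shift,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": r["gene_id"],
                    "distal_control": md, "proximal_control": 0.0,
                    "distal_treated": md, "proximal_treated": 0.0,
                }
            )
    return pd.DataFrame(rows).set_index("gene_id")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, mu * alpha)
    return rng.poisson(lam)


def simulate_pas_counts(
    truth: pd.DataFrame,
    windows,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window 3'end count matrix plus the window truth map.

    Planted positions are located in the supplied (built, filtered)
    window list; genes whose planted window was removed by the
    internal-priming filter are flagged lost in the window truth.
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, w in enumerate(windows):
        if w.kind == "signal":
            trees.setdefault((w.chrom, w.strand), IntervalTree()).addi(w.start, w.end, idx)

    def locate(chrom: str, pos: int, strand: str) -> int | None:
        tree = trees.get((chrom, strand))
        if tree is None or pos < 0:
            return None
        hits = tree.overlap(pos, pos + 1)
        return min(iv.data for iv in hits) if hits else None

    expression = {
        gid: float(cfg.mean_3p_reads * np.exp(rng.normal(0.0, 0.5)))
        for gid in truth["gene_id"]
    }
    masses = expected_pas_masses(truth, cfg, expression)

    n_samples = 2 * cfg.n_replicates
    sample_ids = [f"pas_{cond}_{r}" for cond in ("control", "treated") for r in range(1, cfg.n_replicates + 1)]
    mu = np.zeros((len(windows), n_samples), dtype=float)
    wrows = []
    for _, r in truth.iterrows():
        di = locate(r["chrom"], int(r["distal_pas_pos"]), r["strand"])
        pi = locate(r["chrom"], int(r["proximal_pas_pos"]), r["strand"]) if r["proximal_pas_pos"] >= 0 else None
        m = masses.loc[r["gene_id"]]
        for rep in range(cfg.n_replicates):
            if di is not None:
                mu[di, rep] += m["distal_control"]
                mu[di, cfg.n_replicates + rep] += m["distal_treated"]
            if pi is not None:
                mu[pi, rep] += m["proximal_control"]
                mu[pi, cfg.n_replicates + rep] += m["proximal_treated"]
        wrows.append(
            {
                "gene_id": r["gene_id"],
                "distal_window": windows[di].window_id if di is not None else "",
                "proximal_window": windows[pi].window_id if pi is not None else "",
                "distal_lost": di is None,
                "proximal_lost": r["affected"] and pi is None,
            }
        )

    counts = _nb_sample(rng, mu, cfg.nb_dispersion)
    cdf = pd.DataFrame(counts, index=[w.window_id for w in windows], columns=sample_ids)
    return cdf, pd.DataFrame(wrows).set_index("gene_id")


def simulate_exon_usage(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthetic exon-usage differential table with the shortening signature.

    Affected genes get a 5'-up / 3'-down log2FC gradient along relative
    exon position; unaffected genes are null.  P-values are planted to
    match (small for strong planted effects) and BH-adjusted.
    """
    from .detables import benjamini_hochberg
    from .exon_usage import relative_exon_position

    tmap = truth.set_index("gene_id")
    rows = []
    for g in genes:
        t = g.representative_transcript
        aff = bool(tmap.loc[g.gene_id, "affected"])
        for k, ex in enumerate(t.exons):
            relpos = relative_exon_position(ex, t)
            if aff:
                expected = 1.0 - 3.0 * relpos
                lfc = expected + rng.normal(0.0, 0.3)
                if abs(expected) > 0.4:
                    p = 10.0 ** rng.uniform(-12, -4)
                else:
                    p = rng.uniform(0.02, 1.0)
            else:
                lfc = rng.normal(0.0, 0.2)
                p = rng.uniform(0.0, 1.0)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "exon_id": f"{g.gene_id}:E{k:03d}",
                    "start": ex[0],
                    "end": ex[1],
                    "relative_position": relpos,
                    "log2fc": float(lfc),
                    "pvalue": float(p),
                }
            )
    df = pd.DataFrame(rows)
    df["padj"] = benjamini_hochberg(df["pvalue"].to_numpy())
    return df


@dataclass
class SimulatedDataset:
    cfg: SimulationConfig
    genes: list[GeneModel]
    genome: GenomeSequence
    truth: pd.DataFrame
    chip_tracks: list[CoverageTrack] = field(default_factory=list)
    rna_tracks: list[CoverageTrack] = field(default_factory=list)
    windows: list = field(default_factory=list)
    pas_counts: pd.DataFrame | None = None
    window_truth: pd.DataFrame | None = None
    exon_table: pd.DataFrame | None = None

    def tracks(self, assay: str, condition: str) -> list[CoverageTrack]:
        pool = self.rna_tracks if assay == "nucRNA" else self.chip_tracks
        return [t for t in pool if t.assay == assay and t.condition == condition]


def simulate_dataset(
    cfg: SimulationConfig,
    chip_assays: Sequence[str] = ("RNAPII",),
    with_rna: bool = True,
    with_pas: bool = True,
    with_exons: bool = True,
) -> SimulatedDataset:
    """Run the full generator: annotation, genome, tracks, windows, counts."""
    rng = np.random.default_rng(cfg.seed)
    genes, genome, truth = simulate_annotation(cfg, rng)
    ds = SimulatedDataset(cfg=cfg, genes=genes, genome=genome, truth=truth)
    if chip_assays:
        ds.chip_tracks = simulate_chip_coverage(genes, truth, cfg, rng, genome, chip_assays)
    if with_rna:
        ds.rna_tracks = simulate_rna_coverage(genes, truth, cfg, rng, genome)
    if with_pas:
        from . import pas

        hits = pas.scan_signals(genome)
        runs = pas.scan_oligoA(genome)
        ds.windows = pas.build_windows(hits, runs, genome.chrom_lengths())
        pas.annotate_windows(ds.windows, genes)
        ds.pas_counts, ds.window_truth = simulate_pas_counts(truth, ds.windows, cfg, rng)
    if with_exons:
        ds.exon_table = simulate_exon_usage(genes, truth, rng)
    return ds


def write_fasta(genome: GenomeSequence, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sample_reads_from_profile(
    expected: np.ndarray, n_reads: int, read_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Read start positions drawn proportionally to expected coverage."""
    w = np.clip(np.asarray(expected, dtype=float), 0, None)
    w = w[: len(w) - read_len]
    p = w / w.sum()
    return rng.choice(len(w), size=n_reads, p=p)


def write_synthetic_bam(
    path: str,
    chrom_lengths: Mapping[str, int],
    reads: Sequence[tuple[str, int, int, str, int]],
    read_len: int = 50,
) -> None:
    """Write (chrom, start, end, strand, mapq) reads to a sorted, indexed BAM.

    Synthetic alignments: bases are 'A', qualities flat; used only for
    exercising the alignment input path.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    refs = {c: i for i, c in enumerate(chrom_lengths)}
    reads = sorted(reads, key=lambda r: (refs[r[0]], r[1]))
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, (chrom, s, e, strand, mapq) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"synth{i:07d}"
            a.reference_id = refs[chrom]
            a.reference_start = s
            a.mapping_quality = mapq
            a.cigarstring = f"{e - s}M"
            a.query_sequence = "A" * (e - s)
            a.query_qualities = pysam.qualitystring_to_array("I" * (e - s))
            a.flag = 16 if strand == "-" else 0
            out.write(a)
    pysam.index(path)
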