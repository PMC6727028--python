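"""Scaled metagene profiles with per-bin paired significance testing.

Each qualifying transcript (genomic span >= 3,180 bp) is laid out on a
fixed 360-bin axis: 90 bins of exactly 50 bp covering TSS-3 kb to
TSS+1.5 kb, 180 variable-width bins tiling the remaining gene body
(TSS+1.5 kb to TTS-1.5 kb) with proportionally rounded edges, and 90
bins of 50 bp covering TTS-1.5 kb to TTS+3 kb.  Per-bin mean coverage
is normalized so each transcript's profile sums to one, profiles are
averaged first across genes and then across samples, and control vs
treated profiles are compared per bin with a paired Wilcoxon signed-rank
test, Bonferroni-adjusted across all bins of a panel.  Adjusted
p-values are banded at 1e-15 (red), 1e-10 (orange) and 1e-3 (yellow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .annotation import TranscriptModel, metagene_length_filter
from .coverage import RegionCoverage

N_FLANK_BINS = 90
N_BODY_BINS = 180
FLANK = 3000
INNER = 1500
FLANK_BIN_WIDTH = 50
N_BINS = 2 * N_FLANK_BINS + N_BODY_BINS

BAND_THRESHOLDS = (("red", 1e-15), ("orange", 1e-10), ("yellow", 1e-3))

SEGMENTS = (
    ["tss_flank"] * N_FLANK_BINS + ["body"] * N_BODY_BINS + ["tts_flank"] * N_FLANK_BINS
)


@dataclass
class BinScheme:
    """360 oriented bins for one transcript.

    ``edges`` holds 361 offsets in transcription-direction coordinates,
    where offset 0 is TSS-3000 and the last edge is TTS+3000.
    """

    transcript_id: str
    strand: str
    chrom: str
    span_start: int
    span_end: int
    edges: np.ndarray

    @property
    def segments(self) -> list[str]:
        return list(SEGMENTS)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def genomic_intervals(self) -> list[tuple[int, int]]:
        """Per-bin genomic [start, end) intervals, in bin (5'->3') order."""
        out = []
        for k in range(len(self.edges) - 1):
            a, b = int(self.edges[k]), int(self.edges[k + 1])
            if self.strand == "+":
                out.append((self.span_start - FLANK + a, self.span_start - FLANK + b))
            else:
                out.append((self.span_end + FLANK - b, self.span_end + FLANK - a))
        return out


def build_bins(t: TranscriptModel) -> BinScheme:
    """Construct the 90/180/90 scheme for one transcript.

    Body bin edges sit at INNER*... + round(k*B/180) for k = 0..180 where
    B = genomic_length - 2*INNER, guaranteeing every body bin is at
    least 1 bp for any transcript passing the length filter.
    """
    if not metagene_length_filter(t):
        raise ValueError(
            f"{t.transcript_id}: genomic length {t.genomic_length} below metagene minimum"
        )
    body = t.genomic_length - 2 * INNER
    flank_edges = np.arange(0, FLANK + INNER + 1, FLANK_BIN_WIDTH)  # 91 edges
    body_edges = (FLANK + INNER) + np.floor(
        np.arange(N_BODY_BINS + 1) * body / N_BODY_BINS + 0.5
    ).astype(np.int64)
    tts_edges = (FLANK + INNER + body) + np.arange(0, FLANK + INNER + 1, FLANK_BIN_WIDTH)
    edges = np.concatenate([flank_edges[:-1], body_edges[:-1], tts_edges])
    return BinScheme(
        transcript_id=t.transcript_id,
        strand=t.strand,
        chrom=t.chrom,
        span_start=t.span_start,
        span_end=t.span_end,
        edges=edges,
    )


@dataclass
class MetageneProfile:
    """Normalized 360-bin profile for one (transcript, sample) pair."""

    transcript_id: str
    sample_id: str
    values: np.ndarray | None
    excluded: bool = False


def profile_transcript(rc: RegionCoverage, scheme: BinScheme) -> MetageneProfile:
    """Per-bin mean coverage, normalized to sum to one.

    ``rc`` must span [TSS-3kb, TTS+3kb) oriented 5'->3'.  A transcript
    with zero total signal is flagged excluded for that sample.
    """
    expected = int(scheme.edges[-1])
    if len(rc.values) != expected:
        raise ValueError(
            f"{scheme.transcript_id}: coverage length {len(rc.values)} != scheme span {expected}"
        )
    sums = np.add.reduceat(rc.values, scheme.edges[:-1])
    means = sums / scheme.widths
    total = means.sum()
    if total <= 0:
        return MetageneProfile(scheme.transcript_id, rc.sample_id, None, excluded=True)
    return MetageneProfile(scheme.transcript_id, rc.sample_id, means / total)


def profile_matrix(profiles: Sequence[MetageneProfile]) -> tuple[np.ndarray, list[str]]:
    """Stack included profiles into (n_transcripts, 360); returns ids kept."""
    rows, ids = [], []
    for p in profiles:
        if not p.excluded:
            rows.append(p.values)
            ids.append(p.transcript_id)
    return (np.array(rows) if rows else np.empty((0, N_BINS))), ids


def average_group(profiles_by_sample: Mapping[str, Sequence[MetageneProfile]]) -> np.ndarray:
    """Group mean curve: average first across genes, then across samples.

    A transcript excluded (zero coverage) in one sample drops out of
    that sample's gene-mean only.
    """
    sample_means = []
    for sample_id, profiles in profiles_by_sample.items():
        mat, _ = profile_matrix(profiles)
        if mat.shape[0] == 0:
            continue
        sample_means.append(mat.mean(axis=0))
    if not sample_means:
        raise ValueError("no included profiles in any sample")
    return np.mean(sample_means, axis=0)


def signed_rank_pvalue(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention).  The exact null
    distribution is used for n <= ``exact_max_n`` when the absolute
    differences are tie-free; otherwise the normal approximation with
    continuity correction.  All differences zero gives p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ad = np.abs(d)
    has_ties = np.unique(ad).size < n
    if n <= exact_max_n and not has_ties:
        res = scipy.stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                                   method="exact")
    else:
        res = scipy.stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                                   method="approx", correction=True)
    return float(min(res.pvalue, 1.0))


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def band_for(adj_p: float) -> str:
    for name, thr in BAND_THRESHOLDS:
        if adj_p <= thr:
            return name
    return "none"


@dataclass
class GroupCurve:
    """Per-bin group comparison: condition means, p-values and bands."""

    label: str
    ctrl_mean: np.ndarray
    treated_mean: np.ndarray
    raw_p: np.ndarray
    adj_p: np.ndarray
    bands: list[str] = field(default_factory=list)
    segments: list[str] = field(default_factory=lambda: list(SEGMENTS))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": np.arange(len(self.ctrl_mean)),
                "segment": self.segments[: len(self.ctrl_mean)],
                "ctrl_mean": self.ctrl_mean,
                "treated_mean": self.treated_mean,
                "raw_p": self.raw_p,
                "adj_p": self.adj_p,
                "band": self.bands,
            }
        )


def condition_mean_profiles(
    profiles_by_sample: Mapping[str, Sequence[MetageneProfile]]
) -> tuple[np.ndarray, list[str]]:
    """Per-transcript condition-mean profile matrix.

    Transcripts excluded in any sample of the condition are dropped so
    that downstream pairing stays aligned.  Returns (matrix, ids).
    """
    per_sample: list[dict[str, np.ndarray]] = []
    for sample_id, profiles in profiles_by_sample.items():
        per_sample.append(
            {p.transcript_id: p.values for p in profiles if not p.excluded}
        )
    if not per_sample:
        raise ValueError("no samples")
    common = set(per_sample[0])
    for d in per_sample[1:]:
        common &= set(d)
    ids = sorted(common)
    mat = np.array([np.mean([d[i] for d in per_sample], axis=0) for i in ids])
    return (mat if ids else np.empty((0, N_BINS))), ids


def per_bin_tests(
    ctrl: Mapping[str, Sequence[MetageneProfile]] | np.ndarray,
    treated: Mapping[str, Sequence[MetageneProfile]] | np.ndarray,
    label: str = "",
    n_bins_tested: int | None = None,
    ids_ctrl: Sequence[str] | None = None,
    ids_treated: Sequence[str] | None = None,
) -> GroupCurve:
    """Paired per-bin signed-rank tests between conditions.

    Accepts either per-sample profile mappings (condition means are
    formed per transcript first) or pre-built (n_transcripts, n_bins)
    matrices with matching transcript id lists.  Pairs are formed by
    transcript; transcripts missing from either condition are dropped.
    """
    if isinstance(ctrl, Mapping):
        cmat, cids = condition_mean_profiles(ctrl)
    else:
        cmat, cids = np.asarray(ctrl, dtype=float), list(ids_ctrl or range(len(ctrl)))
    if isinstance(treated, Mapping):
        tmat, tids = condition_mean_profiles(treated)
    else:
        tmat, tids = np.asarray(treated, dtype=float), list(ids_treated or range(len(treated)))

    common = [i for i in cids if i in set(tids)]
    cidx = {i: k for k, i in enumerate(cids)}
    tidx = {i: k for k, i in enumerate(tids)}
    cmat = cmat[[cidx[i] for i in common]]
    tmat = tmat[[tidx[i] for i in common]]
    if cmat.shape[0] < 6:
        raise ValueError(f"need >= 6 paired transcripts, got {cmat.shape[0]}")

    n_bins = cmat.shape[1]
    m = n_bins_tested if n_bins_tested is not None else n_bins
    raw = np.array(
        [signed_rank_pvalue(cmat[:, b], tmat[:, b]) for b in range(n_bins)]
    )
    adj = np.minimum(1.0, raw * m)
    bands = [band_for(p) for p in adj]
    return GroupCurve(
        label=label,
        ctrl_mean=cmat.mean(axis=0),
        treated_mean=tmat.mean(axis=0),
        raw_p=raw,
        adj_p=adj,
        bands=bands,
        segments=list(SEGMENTS) if n_bins == N_BINS else ["body"] * n_bins,
    )


def ratio_profile(
    mark_mean: np.ndarray, rnapii_mean: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Per-bin mark/RNAPII occupancy ratio with a small stabilizer."""
    mark_mean = np.asarray(mark_mean, dtype=float)
    rnapii_mean = np.asarray(rnapii_mean, dtype=float)
    if mark_mean.shape != rnapii_mean.shape:
        raise ValueError("mismatched bin counts between mark and RNAPII curves")
    return (mark_mean + eps) / (rnapii_mean + eps)


def ratio_profiles(
    mark_mat: np.ndarray, rnapii_mat: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Per-transcript ratio vectors (rows pair mark and RNAPII by index)
    so :func:`per_bin_tests` can run on ratios."""
    mark_mat = np.asarray(mark_mat, dtype=float)
    rnapii_mat = np.asarray(rnapii_mat, dtype=float)
    if mark_mat.shape != rnapii_mat.shape:
        raise ValueError("mismatched profile matrices")
    return (mark_mat + eps) / (rnapii_mat + eps)
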