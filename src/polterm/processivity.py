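"""Transcript-shortening statistics from cumulative coverage.

The X% distance of a gene is the minimum distance in bp from the TSS at
which X% of the gene's total read coverage is reached.  The absolute
delta-X% distance is the control X% distance minus the treated one; the
relative delta is the absolute delta divided by gene length, so a
positive relative delta-90% indicates transcript shortening under
treatment.  Genes are classified shortened / extended / unaffected by
fixed thresholds, grouped into length quantiles, and summarized by the
cumulative shortening curve (fraction of genes with relative delta-90%
at or above each grid value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_X = (10, 50, 90)


class UnmeasurableGene(ValueError):
    """Raised when a gene has zero total coverage in a condition."""


@dataclass
class AnalysisThresholds:
    """Printed classification constants (overridable by config).

    shortened_rel: minimum relative delta-90% for the shortened class.
    extended_abs: absolute delta-90% (bp) below which a gene is extended.
    unaffected_abs: |absolute delta-90%| (bp) at or below which a gene is
        unaffected.
    de_lfc / de_p / non_lfc: differential-expression class bands.
    """

    shortened_rel: float = 0.2
    extended_abs: float = -50.0
    unaffected_abs: float = 25.0
    de_lfc: float = 1.0
    de_p: float = 0.01
    non_lfc: float = 0.1


@dataclass
class DistanceRecord:
    gene_id: str
    condition: str
    distances: dict[int, int]  # x -> bp from TSS
    total_coverage: float


@dataclass
class DeltaRecord:
    gene_id: str
    gene_length: int
    abs_delta: dict[int, float]
    rel_delta: dict[int, float]
    shortening_class: str = "unclassified"


def x_distance(values: np.ndarray, x: float) -> int:
    """Minimum d >= 1 with sum(values[:d]) >= (x/100) * sum(values).

    ``values`` is the per-base coverage vector over the gene span,
    oriented 5'->3'.  Zero total coverage raises
    :class:`UnmeasurableGene`.
    """
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        raise UnmeasurableGene("zero total coverage")
    cum = np.cumsum(values)
    thr = (x / 100.0) * total
    idx = int(np.searchsorted(cum, thr, side="left"))
    # guard against float round-off at the boundary
    while idx < len(cum) - 1 and cum[idx] < thr:
        idx += 1
    return idx + 1


def distance_record(
    values: np.ndarray,
    gene_id: str,
    condition: str,
    xs: Sequence[int] = DEFAULT_X,
) -> DistanceRecord:
    return DistanceRecord(
        gene_id=gene_id,
        condition=condition,
        distances={x: x_distance(values, x) for x in xs},
        total_coverage=float(np.asarray(values, dtype=float).sum()),
    )


def delta_distances(ctrl: DistanceRecord, treated: DistanceRecord, length: int) -> DeltaRecord:
    """Absolute (control minus treated, bp) and relative (per gene
    length) delta-X% distances."""
    abs_d = {
        x: float(ctrl.distances[x] - treated.distances[x])
        for x in ctrl.distances
        if x in treated.distances
    }
    rel_d = {x: v / length for x, v in abs_d.items()}
    return DeltaRecord(gene_id=ctrl.gene_id, gene_length=length, abs_delta=abs_d, rel_delta=rel_d)


def classify(d: DeltaRecord, th: AnalysisThresholds | None = None) -> str:
    """Shortened / extended / unaffected by the delta-90% thresholds.

    Precedence: shortened (rel >= 0.2) first, then extended (abs < -50
    bp), then unaffected (|abs| <= 25 bp); anything else is
    unclassified.
    """
    th = th or AnalysisThresholds()
    rel90 = d.rel_delta.get(90)
    abs90 = d.abs_delta.get(90)
    if rel90 is None or abs90 is None:
        return "unclassified"
    if rel90 >= th.shortened_rel:
        cls = "shortened"
    elif abs90 < th.extended_abs:
        cls = "extended"
    elif abs(abs90) <= th.unaffected_abs:
        cls = "unaffected"
    else:
        cls = "unclassified"
    d.shortening_class = cls
    return cls


def quantile_groups(
    gene_ids: Sequence[str], lengths: Sequence[float], k: int
) -> dict[str, int]:
    """Rank-based equal-size length groups (0 = shortest).

    Ties are broken by gene id order; group sizes differ by at most
    one (larger groups first).
    """
    n = len(gene_ids)
    if k > n:
        raise ValueError(f"requested {k} groups for {n} genes")
    order = sorted(range(n), key=lambda i: (lengths[i], gene_ids[i]))
    out: dict[str, int] = {}
    for gidx, chunk in enumerate(np.array_split(np.array(order), k)):
        for i in chunk:
            out[gene_ids[int(i)]] = gidx
    return out


def shortening_curve(
    rel_delta90: Mapping[str, float],
    grid: Sequence[float],
    groups: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Fraction of genes with relative delta-90% >= each grid value.

    With ``groups``, one curve per group; the curve is monotone
    non-increasing along an ascending grid.
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    if groups is None:
        groups = {g: 0 for g in rel_delta90}
    rows = []
    for gidx in sorted(set(groups.values())):
        vals = np.array([v for g, v in rel_delta90.items() if groups.get(g) == gidx])
        if vals.size == 0:
            raise ValueError(f"group {gidx} is empty")
        for x in grid:
            rows.append(
                {"group": gidx, "grid": x, "fraction": float(np.mean(vals >= x))}
            )
    return pd.DataFrame(rows)


def distance_table(
    genes,
    ctrl_tracks,
    treated_tracks,
    xs: Sequence[int] = DEFAULT_X,
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene X% distances, deltas and shortening class.

    Coverage per condition is the replicate-mean RPM vector over the
    representative transcript's full genomic span (introns included).
    Genes with zero coverage in either condition are excluded and
    listed in the ``dropped`` attribute of the returned frame.
    """
    from .coverage import condition_mean_rpm

    thresholds = thresholds or AnalysisThresholds()
    rows, dropped = [], []
    for g in genes:
        t = g.representative_transcript
        try:
            cv = condition_mean_rpm(ctrl_tracks, t.chrom, t.span_start, t.span_end, t.strand)
            tv = condition_mean_rpm(treated_tracks, t.chrom, t.span_start, t.span_end, t.strand)
            rc = distance_record(cv.values, g.gene_id, "control", xs)
            rt = distance_record(tv.values, g.gene_id, "treated", xs)
        except UnmeasurableGene:
            dropped.append(g.gene_id)
            continue
        d = delta_distances(rc, rt, t.genomic_length)
        cls = classify(d, thresholds)
        row = {"gene_id": g.gene_id, "length": t.genomic_length, "class": cls}
        for x in xs:
            row[f"d{x}_ctrl"] = rc.distances[x]
            row[f"d{x}_treated"] = rt.distances[x]
            row[f"abs_delta{x}"] = d.abs_delta[x]
            row[f"rel_delta{x}"] = d.rel_delta[x]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["dropped"] = dropped
    return df
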