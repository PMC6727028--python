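"""Positional analysis of differential exon usage.

Exon-level differential-usage results (DEXSeq-style tables) are placed
along the gene axis by relative position (0 at the gene 5' end, 1 at
the 3' end, strand-aware, using the exon midpoint), summarized per
position decile, and cross-tabulated against gene-level expression
classes.  A 3'-biased accumulation of down-regulated exons, mirrored
by up-regulated exons at the 5' end, is the exon-level signature of
transcript shortening.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel

log = logging.getLogger(__name__)


def relative_exon_position(exon: tuple[int, int], t: TranscriptModel) -> float:
    """Oriented distance from the TSS to the exon midpoint, over gene length.

    Clamped to [0, 1].  The exon must lie within the transcript span.
    """
    s, e = exon
    if s < t.span_start or e > t.span_end:
        raise ValueError(
            f"exon [{s}, {e}) outside transcript span [{t.span_start}, {t.span_end})"
        )
    mid = (s + e) / 2.0
    if t.strand == "+":
        pos = (mid - t.span_start) / t.genomic_length
    else:
        pos = (t.span_end - mid) / t.genomic_length
    return float(min(1.0, max(0.0, pos)))


def fraction_differential(
    exon_table: pd.DataFrame,
    p_cut: float = 0.01,
    direction: str | None = None,
) -> float | None:
    """Fraction of a gene's tested exons that are significantly
    differentially used (optionally in one direction).

    ``exon_table`` holds one gene's exons with ``log2fc`` and ``padj``
    columns; exons with missing adjusted p are not tested.  Returns
    None (and logs) when no exon was tested.
    """
    tested = exon_table[exon_table["padj"].notna()]
    if len(tested) == 0:
        log.info("gene has zero tested exons; excluded")
        return None
    sig = tested["padj"] < p_cut
    if direction == "up":
        sig &= tested["log2fc"] > 0
    elif direction == "down":
        sig &= tested["log2fc"] < 0
    return float(sig.sum() / len(tested))


def add_relative_positions(
    exon_table: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Attach relative_position to an exon table with gene_id/start/end."""
    by_gene = {g.gene_id: (g.representative_transcript if g.representative else g.transcripts[0]) for g in genes}
    pos = []
    for _, row in exon_table.iterrows():
        t = by_gene[row["gene_id"]]
        pos.append(relative_exon_position((int(row["start"]), int(row["end"])), t))
    out = exon_table.copy()
    out["relative_position"] = pos
    return out


def usage_by_position_deciles(records: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Per-decile summary of exon-usage log2 fold-changes.

    Exons are assigned to deciles by the rank of their relative
    position (counts per decile differ by at most one); the summary
    reports median and quartiles of log2FC per decile.
    """
    if len(records) < k:
        raise ValueError(f"need >= {k} records, got {len(records)}")
    order = records.sort_values(
        ["relative_position", "gene_id", "exon_id"], kind="mergesort"
    ).index.to_numpy()
    decile = np.empty(len(records), dtype=int)
    for d, chunk in enumerate(np.array_split(order, k)):
        for i in chunk:
            decile[records.index.get_loc(i)] = d
    out = records.copy()
    out["decile"] = decile
    summary = (
        out.groupby("decile")["log2fc"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n="size",
        )
        .reset_index()
    )
    return summary


def overlap_sets(
    gene_classes: Mapping[str, str],
    exon_table: pd.DataFrame,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Cross-tabulate gene expression classes against per-gene exon calls.

    Restricted to genes present in the exon-level table (the exon-test
    universe).  Raises when the universes are disjoint.
    """
    exon_genes = set(exon_table["gene_id"])
    universe = exon_genes & set(gene_classes)
    if not universe:
        raise ValueError("gene-level and exon-level universes are disjoint")

    has_down, has_up = {}, {}
    for gid, sub in exon_table.groupby("gene_id"):
        tested = sub[sub["padj"].notna()]
        has_down[gid] = bool(((tested["padj"] < p_cut) & (tested["log2fc"] < 0)).any())
        has_up[gid] = bool(((tested["padj"] < p_cut) & (tested["log2fc"] > 0)).any())

    rows = []
    for gcls in ("down", "up", "non", "other"):
        members = [g for g in universe if gene_classes[g] == gcls]
        n = len(members)
        nd = sum(has_down.get(g, False) for g in members)
        nu = sum(has_up.get(g, False) for g in members)
        rows.append(
            {
                "gene_class": gcls,
                "n_genes": n,
                "n_with_down_exon": nd,
                "n_with_up_exon": nu,
                "frac_with_down_exon": nd / n if n else 0.0,
                "frac_with_up_exon": nu / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
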