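"""High-level analysis runs chaining the pipeline stages.

These helpers wire the stage modules together the way a full analysis
would: distance tables and shortening classification from nuclear RNA
coverage, metagene group comparisons from ChIP coverage, and the
poly(A)-window regulation summary from 3'end counts.  They are shared
by the command-line interface, the acceptance script and the
end-to-end tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import detables, metagene, pas, processivity
from .simulate import SimulatedDataset


def metagene_group_comparison(
    ds: SimulatedDataset,
    gene_ids: Sequence[str],
    assay: str = "RNAPII",
    label: str = "",
) -> metagene.GroupCurve:
    """Per-bin paired comparison of control vs treated profiles for a gene group."""
    genes = [g for g in ds.genes if g.gene_id in set(gene_ids)]
    profiles: dict[str, dict[str, list]] = {"control": {}, "treated": {}}
    for condition in ("control", "treated"):
        for track in ds.tracks(assay, condition):
            plist = profiles[condition].setdefault(track.sample_id, [])
            for g in genes:
                t = g.representative_transcript
                scheme = metagene.build_bins(t)
                from .coverage import extract_region

                rc = extract_region(
                    track, t.chrom, t.span_start - metagene.FLANK,
                    t.span_end + metagene.FLANK, t.strand, g.gene_id,
                )
                plist.append(metagene.profile_transcript(rc, scheme))
    return metagene.per_bin_tests(profiles["control"], profiles["treated"], label=label)


def distance_analysis(ds: SimulatedDataset) -> pd.DataFrame:
    """Per-gene X% distance table from nuclear RNA coverage."""
    ctrl = ds.tracks("nucRNA", "control")
    trt = ds.tracks("nucRNA", "treated")
    return processivity.distance_table(ds.genes, ctrl, trt)


def recovery_stats(ds: SimulatedDataset, dist: pd.DataFrame, t_cap: float = 0.7) -> dict:
    """Truth-recovery metrics for the shortening classification.

    Precision/recall of predicted-shortened vs truth-affected
    (recall restricted to affected genes with t <= ``t_cap``, where the
    closed-form expected relative delta-90%, 0.9*(1-t), clears the 0.2
    threshold with margin), and the per-truncation-stratum median error
    of recovered relative delta-90% against 0.9*(1-t).
    """
    merged = dist.merge(ds.truth[["gene_id", "affected", "t"]], on="gene_id")
    pred = merged["class"] == "shortened"
    true = merged["affected"]

    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    recall_pool = merged[true & (merged["t"] <= t_cap)]
    rec_tp = int((recall_pool["class"] == "shortened").sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = rec_tp / len(recall_pool) if len(recall_pool) else float("nan")

    aff = merged[true].copy()
    aff["expected_rel90"] = 0.9 * (1.0 - aff["t"])
    aff["stratum"] = np.floor(aff["t"] * 10).astype(int)
    stratum_err = (
        aff.groupby("stratum")
        .apply(
            lambda s: float(np.median(s["rel_delta90"]) - np.median(s["expected_rel90"])),
            include_groups=False,
        )
        .to_dict()
    )
    return {
        "precision": precision,
        "recall": recall,
        "stratum_median_error": stratum_err,
        "max_abs_stratum_error": max(abs(v) for v in stratum_err.values())
        if stratum_err
        else float("nan"),
    }


def pas_analysis(
    ds: SimulatedDataset,
    dist: pd.DataFrame,
    min_total: int = 10,
    alpha: float = 0.01,
) -> tuple[list, pd.DataFrame, dict]:
    """Window regulation calls and the per-gene poly(A)-site summary.

    Windows with fewer than ``min_total`` reads overall are left
    untested (mirroring independent filtering in count-based
    differential testing); the rest are tested with the pooled-binomial
    stand-in engine and called at adjusted p < ``alpha``.
    """
    counts = ds.pas_counts
    design = ["control"] * ds.cfg.n_replicates + ["treated"] * ds.cfg.n_replicates
    tested = counts[counts.sum(axis=1) >= min_total]
    de = detables.standin_de_test(tested, design, reference="control", method="pooled-binomial")
    pas.call_regulated_pas(ds.windows, de, alpha=alpha)

    classes = dict(zip(dist["gene_id"], dist["class"]))
    summary = pas.summarize_genes(ds.genes, ds.windows, classes)

    shortened = summary[summary["transcript_class"] == "shortened"]
    with_down = shortened[shortened["has_down_utr3_pas"]]
    frac_down = len(with_down) / len(shortened) if len(shortened) else float("nan")
    frac_up = (
        float((with_down["has_upstream_up_pas"]).mean()) if len(with_down) else float("nan")
    )
    frac_multi = (
        float((with_down["n_upstream_up"] >= 2).mean()) if len(with_down) else float("nan")
    )
    stats = {
        "n_shortened": int(len(shortened)),
        "frac_shortened_with_down_utr3_pas": frac_down,
        "frac_down_with_upstream_up": frac_up,
        "frac_down_with_multiple_upstream_up": frac_multi,
    }
    return ds.windows, summary, stats


def significant_band_fractions(curve: metagene.GroupCurve) -> dict:
    """Fraction of significant deficit bins per metagene segment.

    A bin counts when its Bonferroni-adjusted p is at or below 1e-3 and
    the treated mean lies below the control mean (the 3' deficit
    direction).
    """
    seg = np.array(curve.segments)
    sig = (curve.adj_p <= 1e-3) & (curve.treated_mean < curve.ctrl_mean)
    out = {}
    for name in ("tss_flank", "body", "tts_flank"):
        mask = seg == name
        out[name] = float(sig[mask].mean()) if mask.any() else float("nan")
    return out
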